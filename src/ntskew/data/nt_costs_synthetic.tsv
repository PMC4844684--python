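# Synthetic stand-in nucleotide cost table (ATP-equivalent high-energy
# phosphate bonds per RNA nucleotide, de novo synthesis). Values are NOT
# measured; they are constructed to satisfy every ordering reported for
# E. coli de novo synthesis costs: G > A, C > U/T, G > C, A > U/T, and
# G + C > A + U. Magnitudes are in the range of published FBA estimates.
name	cost	source
A	45.0	synthetic_ordering_consistent
C	43.2	synthetic_ordering_consistent
G	47.7	synthetic_ordering_consistent
U	40.4	synthetic_ordering_consistent
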