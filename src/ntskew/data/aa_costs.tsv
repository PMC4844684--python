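name	cost	source
A	11.7	akashi_gojobori_ecoli
R	27.3	akashi_gojobori_ecoli
N	14.7	akashi_gojobori_ecoli
D	12.7	akashi_gojobori_ecoli
C	24.7	akashi_gojobori_ecoli
Q	16.3	akashi_gojobori_ecoli
E	15.3	akashi_gojobori_ecoli
G	11.7	akashi_gojobori_ecoli
H	38.3	akashi_gojobori_ecoli
I	32.3	akashi_gojobori_ecoli
L	27.3	akashi_gojobori_ecoli
K	30.3	akashi_gojobori_ecoli
M	34.3	akashi_gojobori_ecoli
F	52.0	akashi_gojobori_ecoli
P	20.3	akashi_gojobori_ecoli
S	11.7	akashi_gojobori_ecoli
T	18.7	akashi_gojobori_ecoli
W	74.3	akashi_gojobori_ecoli
Y	50.0	akashi_gojobori_ecoli
V	23.3	akashi_gojobori_ecoli
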