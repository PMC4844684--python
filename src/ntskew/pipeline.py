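"""End-to-end orchestration: genome -> counts -> skews -> parameter estimates."""

from __future__ import annotations

import logging

from .genome_io import AnnotatedGenome, extract_interoperonic, rotate_to_origin
from .model import fit_global
from .sites import SiteCounts, SkewSet, count_sites, observed_skews

log = logging.getLogger(__name__)


def genome_counts(genome: AnnotatedGenome, min_len: int = 100, trim5: int = 60) -> SiteCounts:
    """Rotate to the origin, extract interoperonic regions, tally sites."""
    rotated = rotate_to_origin(genome)
    regions = extract_interoperonic(rotated, min_len=min_len, trim5=trim5)
    return count_sites(rotated, regions)


def genome_skews(genome: AnnotatedGenome) -> SkewSet:
    return observed_skews(genome_counts(genome))


def analyze_cohort(skew_sets: list[SkewSet], n_boot: int = 0, seed: int = 1):
    """Global tau/f fit plus per-genome decomposition for a genome cohort."""
    return fit_global(skew_sets, n_boot=n_boot, seed=seed)
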