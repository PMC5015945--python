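"""Pipeline configuration and reproducible random-number streams."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np


def rng_stream(seed: int, stage: str) -> np.random.Generator:
    """A Generator keyed by (seed, stage name).

    Every stochastic stage of the pipeline draws from its own stream so
    that re-running a single stage reproduces its draws regardless of
    what ran before it.
    """
    return np.random.default_rng([int(seed) & 0x7FFFFFFF, zlib.crc32(stage.encode())])


@dataclass
class ScoringScheme:
    """Nucleotide local-alignment scoring (BLASTN-style).

    Match/mismatch are rewards; gap_open/gap_extend are costs, so a gap
    of length L subtracts ``gap_open + gap_extend * L``. Karlin-Altschul
    lambda is derived from the match/mismatch scores under uniform base
    frequencies; K is a fixed calibration constant.
    """

    match: int = 1
    mismatch: int = -2
    gap_open: int = 5
    gap_extend: int = 2
    word_size: int = 8
    ka_K: float = 0.46

    _lambda_cache: float | None = field(default=None, repr=False, compare=False)

    @property
    def ka_lambda(self) -> float:
        if self._lambda_cache is None:
            object.__setattr__(self, "_lambda_cache", karlin_altschul_lambda(self.match, self.mismatch))
        return self._lambda_cache

    def evalue(self, score: float, query_len: int, db_len: int) -> float:
        """E = K * m * n * exp(-lambda * S)."""
        return self.ka_K * query_len * db_len * float(np.exp(-self.ka_lambda * score))


def karlin_altschul_lambda(match: int, mismatch: int) -> float:
    """Solve sum_ij p_i p_j exp(lambda * s_ij) = 1 for lambda > 0.

    Uniform base frequencies: 4/16 cells score `match`, 12/16 `mismatch`.
    """
    from scipy.optimize import brentq

    if match <= 0 or mismatch >= 0:
        raise ValueError("need match > 0 and mismatch < 0")

    def f(lam: float) -> float:
        return 0.25 * np.exp(lam * match) + 0.75 * np.exp(lam * mismatch) - 1.0

    return float(brentq(f, 1e-9, 10.0))


@dataclass
class PipelineConfig:
    """All thresholds of the homology/families/loss-decay/features stages.

    Defaults follow the published protocol: strict E-value 1e-20 for
    homolog calls, relaxed 1e-5 for the loss/decay re-search, 5 kb
    flanks when anchor genes are absent, 10 kb decay linkage, at least 4
    species spanning both lineages for a conserved family, >100 aa ORF
    filter, >=10 nt TE overlap with 100/500 bp adjacency classes, 100
    bootstrap replicates, 70% support collapse, >3 backbone duplications
    exclusion, and miRNA expectation cutoff 2.0 over 20-nt windows.
    """

    scoring: ScoringScheme = field(default_factory=ScoringScheme)
    strict_evalue: float = 1e-20
    relaxed_evalue: float = 1e-5
    synteny_window_bp: int = 50_000
    flank_bp_when_no_gene: int = 5_000
    decay_link_bp: int = 10_000
    min_family_species: int = 4
    orf_aa_threshold: int = 100
    te_min_overlap_nt: int = 10
    te_near_bp: tuple[int, int] = (100, 500)
    bootstrap_reps: int = 100
    support_collapse_pct: float = 70.0
    max_backbone_dups: int = 3
    mirna_expectation_cutoff: float = 2.0
    mirna_score_len: int = 20
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.strict_evalue < self.relaxed_evalue:
            raise ValueError("strict_evalue must be < relaxed_evalue")
        for name in ("synteny_window_bp", "flank_bp_when_no_gene", "decay_link_bp",
                     "min_family_species", "orf_aa_threshold", "te_min_overlap_nt",
                     "bootstrap_reps", "mirna_score_len"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 < self.support_collapse_pct <= 100):
            raise ValueError("support_collapse_pct must be in (0, 100]")

    def rng(self, stage: str) -> np.random.Generator:
        return rng_stream(self.rng_seed, stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["scoring"].pop("_lambda_cache", None)
        return d
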