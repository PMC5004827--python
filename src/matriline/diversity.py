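"""Gene diversity (h) and nucleotide diversity (pi) with variance estimates.

h is the probability that two lineages drawn at random from the sample
carry different haplotypes, h = [n/(n-1)](1 - sum p_i^2); its analytic
variance is Nei's estimator

    V(h) = 2/[n(n-1)] * { 2(n-2)[sum p_i^3 - (sum p_i^2)^2]
                          + sum p_i^2 - (sum p_i^2)^2 }.

pi is the mean per-site pairwise distance within the sample (K2P by
default) with a standard error from a bootstrap over alignment columns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import distances as _dist
from .haplotypes import classify_sites, collapse_haplotypes
from .seq_io import AlignedSequenceSet, SampleMetadata


@dataclass(frozen=True)
class GeneDiversity:
    h: float
    se_analytic: float
    se_resample: float | None = None

    @property
    def se(self) -> float:
        return self.se_analytic


def _h_from_counts(counts: np.ndarray) -> float:
    n = counts.sum()
    p = counts / n
    return (n / (n - 1)) * (1.0 - float((p ** 2).sum()))


def gene_diversity(
    haplotype_counts: Sequence[int],
    n_resamples: int = 0,
    seed: int | None = 0,
) -> GeneDiversity:
    """Unbiased gene diversity with analytic and optional resampling SE.

    Parameters
    ----------
    haplotype_counts : sequence of positive int
        Carrier counts per haplotype; their sum n must be >= 2.
    n_resamples : int
        If > 0, additionally estimate the SE by resampling n individuals
        with replacement this many times (the permutation-style variance
        assessment; 10,000 is the conventional count).
    """
    counts = np.asarray(list(haplotype_counts), dtype=float)
    if counts.size == 0 or np.any(counts < 1) or np.any(counts != np.floor(counts)):
        raise ValueError("haplotype counts must be positive integers")
    n = int(counts.sum())
    if n < 2:
        raise ValueError("gene diversity requires n >= 2")

    p = counts / n
    sp2 = float((p ** 2).sum())
    sp3 = float((p ** 3).sum())
    var = (2.0 / (n * (n - 1))) * (2.0 * (n - 2) * (sp3 - sp2 ** 2) + sp2 - sp2 ** 2)
    se_analytic = math.sqrt(max(var, 0.0))
    h = _h_from_counts(counts)

    se_resample = None
    if n_resamples > 0:
        rng = np.random.default_rng(seed)
        reps = np.empty(n_resamples)
        for r in range(n_resamples):
            draw = rng.choice(counts.size, size=n, replace=True, p=p)
            c = np.bincount(draw, minlength=counts.size).astype(float)
            c = c[c > 0]
            reps[r] = _h_from_counts(c)
        se_resample = float(reps.std(ddof=1))
    return GeneDiversity(h=h, se_analytic=se_analytic, se_resample=se_resample)


@dataclass(frozen=True)
class NucleotideDiversity:
    pi: float
    se: float
    model: str


def nucleotide_diversity(
    alignment: AlignedSequenceSet,
    ids: Sequence[str] | None = None,
    model: str = "k2p",
    n_bootstrap: int = 1000,
    seed: int | None = 0,
) -> NucleotideDiversity:
    """Mean per-site pairwise distance over all unordered pairs.

    The SE is the standard deviation of pi over ``n_bootstrap`` column
    resamples (0 disables it). The distance kernel is pluggable
    (``k2p``, ``jc69``, ``p``).
    """
    ids = list(ids) if ids is not None else list(alignment.ids)
    if len(ids) < 2:
        raise ValueError("nucleotide diversity requires >= 2 sequences")

    if model == "k2p":
        ts, tv, ok, pairs = _dist._pair_indicators(alignment, ids, None, within=True)
        pi = _dist._mean_k2p(ts, tv, ok, pairs=pairs)
        se = 0.0
        if n_bootstrap > 0:
            rng = np.random.default_rng(seed)
            L = alignment.length
            reps = np.empty(n_bootstrap)
            for r in range(n_bootstrap):
                reps[r] = _dist._mean_k2p(ts, tv, ok, rng.integers(0, L, size=L), pairs)
            se = float(reps.std(ddof=1))
        return NucleotideDiversity(pi=pi, se=se, model=model)

    # generic (slower) path for alternative kernels
    pi = _dist.mean_pairwise_distance(alignment, ids, model=model)
    se = 0.0
    if n_bootstrap > 0:
        rng = np.random.default_rng(seed)
        L = alignment.length
        sub = alignment.subset(ids)
        reps = np.empty(n_bootstrap)
        for r in range(n_bootstrap):
            cols = rng.integers(0, L, size=L)
            boot = AlignedSequenceSet(
                ids=sub.ids,
                seqs=tuple("".join(s[j] for j in cols) for s in sub.seqs),
                filter_mode=sub.filter_mode,
            )
            reps[r] = _dist.mean_pairwise_distance(boot, list(boot.ids), model=model)
        se = float(reps.std(ddof=1))
    return NucleotideDiversity(pi=pi, se=se, model=model)


@dataclass(frozen=True)
class DiversityResult:
    """One species row of the diversity summary table."""

    species: str
    n: int
    h: float
    h_se: float
    pi: float
    pi_se: float
    n_haplotypes: int
    n_variable_sites: int
    n_informative_sites: int


def species_diversity_table(
    alignment: AlignedSequenceSet,
    metadata: SampleMetadata,
    model: str = "k2p",
    n_bootstrap: int = 1000,
    n_resamples: int = 0,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Per-species diversity summary (species with >= 2 sampled individuals).

    Columns: species, n, h, h_se, pi, pi_se, n_haplotypes,
    n_variable_sites, n_informative_sites.
    """
    rows = []
    for species, ids in metadata.by_species().items():
        ids = [i for i in ids if i in set(alignment.ids)]
        if len(ids) < 2:
            continue
        sub = alignment.subset(ids)
        table = collapse_haplotypes(sub)
        sites = classify_sites(sub)
        gd = gene_diversity(table.counts(), n_resamples=n_resamples, seed=seed)
        nd = nucleotide_diversity(
            alignment, ids, model=model, n_bootstrap=n_bootstrap, seed=seed
        )
        h_se = gd.se_resample if (n_resamples > 0 and gd.se_resample is not None) else gd.se_analytic
        rows.append(
            DiversityResult(
                species=species,
                n=len(ids),
                h=gd.h,
                h_se=h_se,
                pi=nd.pi,
                pi_se=nd.se,
                n_haplotypes=len(table),
                n_variable_sites=sites.n_variable,
                n_informative_sites=sites.n_informative,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])
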