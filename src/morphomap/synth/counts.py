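"""Negative-binomial count matrices with planted phenotype signatures.

Emulates bulk RNA-seq of organoid phenotypes (a few replicates per
phenotype): gene-wise baseline means drawn log-normally, NB sampling with
a common dispersion, per-sample library-size factors, and a block of
"planted" genes per phenotype whose mean is up-shifted by a known log2
fold change only in the samples of that phenotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass
class CountTruth:
    counts: pd.DataFrame            # genes x samples, int
    phenotype_labels: pd.Series     # per sample
    planted_genes: dict[str, list[str]]
    true_log2fc: float
    dispersion: float
    library_size_factors: pd.Series

    def __post_init__(self):
        sets = list(self.planted_genes.values())
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                if set(sets[i]) & set(sets[j]):
                    raise ValueError("planted gene sets must be disjoint")


def generate_count_matrix(
    n_genes: int = 2000,
    phenotypes: tuple[str, ...] = ("A", "B", "C"),
    replicates: int = 3,
    planted_per_phenotype: int = 50,
    log2fc: float = 3.0,
    dispersion: float = 0.1,
    depth_range: tuple[float, float] = (0.5, 2.0),
    base_mean_log_mu: float = 4.0,
    base_mean_log_sigma: float = 1.0,
    seed: int = 0,
) -> CountTruth:
    """Simulate a phenotype-labelled NB count matrix.

    Baseline per-gene means are ``exp(N(base_mean_log_mu,
    base_mean_log_sigma))``; counts are NB with variance
    ``mu + dispersion * mu**2`` (Poisson in the ``dispersion -> 0``
    limit).  ``planted_per_phenotype`` genes per phenotype are up-shifted
    by ``log2fc`` in their own phenotype's samples only; the planted
    blocks are disjoint.
    """
    if replicates != int(replicates) or replicates < 1:
        raise ValueError("replicates must be a positive integer")
    n_ph = len(phenotypes)
    if planted_per_phenotype * n_ph >= n_genes:
        raise ValueError("too many planted genes for the gene universe")
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    lo, hi = depth_range
    if not 0 < lo <= hi:
        raise ValueError("depth_range must be positive and ordered")

    rng = np.random.default_rng(seed)
    genes = [f"gene_{i:05d}" for i in range(n_genes)]
    samples, labels = [], []
    for ph in phenotypes:
        for r in range(int(replicates)):
            samples.append(f"{ph}_rep{r + 1}")
            labels.append(ph)
    n_samples = len(samples)

    base = np.exp(rng.normal(base_mean_log_mu, base_mean_log_sigma, size=n_genes))
    sf = rng.uniform(lo, hi, size=n_samples)

    mu = np.outer(base, sf)
    planted: dict[str, list[str]] = {}
    for k, ph in enumerate(phenotypes):
        idx = np.arange(k * planted_per_phenotype, (k + 1) * planted_per_phenotype)
        cols = [j for j, lab in enumerate(labels) if lab == ph]
        mu[np.ix_(idx, cols)] *= 2.0 ** log2fc
        planted[ph] = [genes[i] for i in idx]

    if dispersion > 0:
        n_param = 1.0 / dispersion
        counts = rng.negative_binomial(n_param, n_param / (n_param + mu))
    else:
        counts = rng.poisson(mu)

    return CountTruth(
        counts=pd.DataFrame(counts, index=genes, columns=samples),
        phenotype_labels=pd.Series(labels, index=samples, name="phenotype"),
        planted_genes=planted,
        true_log2fc=log2fc,
        dispersion=dispersion,
        library_size_factors=pd.Series(sf, index=samples, name="size_factor"),
    )
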