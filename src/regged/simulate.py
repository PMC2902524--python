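"""Synthetic-data generators with known ground truth for every pipeline input.

The compartment-pair generator emulates the statistical structure of a
paired glomerulus / tubulointerstitium microarray comparison after RMA-style
normalisation: ~22k probesets, six samples per compartment, log2 values
centred around 7 with spread ~2, Gaussian measurement noise on the log2
scale, a single affine systematic distortion between the two compartments,
and a small known subset of glomerulus-enriched probesets.

The tubulointerstitial compartment is generated by *inverting* the
adjustment direction used downstream (tubulointerstitium -> glomeruli), so
that a perfect calibration recovers the configured distortion; parameter
recovery is therefore the natural end-to-end test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .calibration import LinearMap
from .io import AnnotationTable, CtTable, ExpressionMatrix, LibraryCounts

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "simulate_compartment_pair",
    "simulate_annotation",
    "simulate_library_counts",
    "simulate_ct_table",
]

#: The default affine distortion between compartments matches the magnitude
#: of the systematic offset observed between separately-normalised renal
#: compartment profiles (final adjustment map slope ~0.94, intercept ~1.18).
DEFAULT_DISTORTION = LinearMap(slope=0.9392425, intercept=1.17905)


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the simulated compartment comparison.

    Defaults mirror an HG-U133A-scale design: 22,283 probesets, six living
    donors per compartment, log2 baseline Normal(7, 2^2), per-measurement
    noise SD 0.3 log2 units, 3% of probesets glomerulus-enriched by
    2 log2 units (4-fold).
    """

    n_probesets: int = 22283
    n_samples_per_compartment: int = 6
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    noise_sd: float = 0.3
    distortion: LinearMap = DEFAULT_DISTORTION
    enriched_fraction: float = 0.03
    enrichment_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_probesets < 2:
            raise ValueError("n_probesets must be >= 2")
        if self.n_samples_per_compartment < 1:
            raise ValueError("n_samples_per_compartment must be >= 1")
        if self.baseline_sd < 0 or self.noise_sd < 0:
            raise ValueError("standard deviations must be >= 0")
        if not 0 <= self.enriched_fraction < 1:
            raise ValueError("enriched_fraction must be in [0, 1)")
        if self.distortion.slope == 0:
            raise ValueError("distortion slope must be non-zero (map must be invertible)")

    @property
    def n_enriched(self) -> int:
        return round(self.enriched_fraction * self.n_probesets)

    def with_(self, **kwargs) -> "SimulationConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth of one simulated compartment pair."""

    enriched_probeset_ids: tuple[str, ...]
    distortion: LinearMap
    true_mu: pd.Series  # per-probeset true glomerular baseline (log2)


def _probeset_ids(n: int) -> list[str]:
    width = max(5, len(str(n)))
    return [f"PS{i:0{width}d}" for i in range(1, n + 1)]


def simulate_compartment_pair(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SimulationTruth]:
    """Draw a paired glomerular / tubulointerstitial expression matrix.

    Per-probeset true level mu_i ~ Normal(baseline_mean, baseline_sd^2).
    Glomerular samples are mu_i (+ enrichment_effect for the enriched
    subset) plus Normal(0, noise_sd^2) noise.  Tubulointerstitial samples
    are (mu_i - b*) / a* plus noise, i.e. the inverse of the downstream
    tub -> glom adjustment map (a*, b*).  Identical seeds give bit-identical
    output.
    """
    n, m = config.n_probesets, config.n_samples_per_compartment
    streams = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(4)]
    rng_mu, rng_pick, rng_glom, rng_tub = streams

    ids = _probeset_ids(n)
    mu = rng_mu.normal(config.baseline_mean, config.baseline_sd, size=n)

    n_enriched = config.n_enriched
    enriched_idx = np.sort(rng_pick.choice(n, size=n_enriched, replace=False))
    enriched_ids = tuple(ids[i] for i in enriched_idx)

    glom_level = mu.copy()
    glom_level[enriched_idx] += config.enrichment_effect
    tub_level = config.distortion.inverted()(mu)

    glom_values = glom_level[:, None] + rng_glom.normal(0.0, config.noise_sd, size=(n, m))
    tub_values = tub_level[:, None] + rng_tub.normal(0.0, config.noise_sd, size=(n, m))

    glom = ExpressionMatrix(
        data=pd.DataFrame(glom_values, index=ids, columns=[f"glom_{j+1}" for j in range(m)]),
        compartment_label="glomerulus",
    )
    tub = ExpressionMatrix(
        data=pd.DataFrame(tub_values, index=ids, columns=[f"tub_{j+1}" for j in range(m)]),
        compartment_label="tubulointerstitium",
    )
    truth = SimulationTruth(
        enriched_probeset_ids=enriched_ids,
        distortion=config.distortion,
        true_mu=pd.Series(mu, index=ids, name="true_mu"),
    )
    return glom, tub, truth


def simulate_annotation(
    n_probesets: int,
    unannotated_rate: float = 0.05,
    redundancy_rate: float = 0.15,
    seed: int = 0,
    probeset_ids: Sequence[str] | None = None,
) -> AnnotationTable:
    """Random probeset -> symbol table with controlled annotation gaps and
    platform redundancy.

    Exactly ``round(unannotated_rate * n)`` probesets get an empty symbol and
    ``round(redundancy_rate * n)`` get a symbol already used by another
    probeset, so n annotated probesets map to n_annotated - n_redundant
    distinct symbols.
    """
    if not 0 <= unannotated_rate < 1 or not 0 <= redundancy_rate < 1:
        raise ValueError("rates must be in [0, 1)")
    ids = list(probeset_ids) if probeset_ids is not None else _probeset_ids(n_probesets)
    if len(ids) != n_probesets:
        raise ValueError("probeset_ids length must equal n_probesets")
    n_unann = round(unannotated_rate * n_probesets)
    n_redundant = round(redundancy_rate * n_probesets)
    n_annotated = n_probesets - n_unann
    if n_redundant > max(n_annotated - 1, 0):
        raise ValueError("redundancy_rate too high for the number of annotated probesets")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    order = rng.permutation(n_probesets)
    unannotated = set(order[:n_unann])
    redundant = order[n_unann : n_unann + n_redundant]

    width = max(5, len(str(n_probesets)))
    symbols = ["" for _ in ids]
    base_counter = 0
    base_symbols: list[str] = []
    for i in order[n_unann + n_redundant :]:
        base_counter += 1
        sym = f"GENE{base_counter:0{width}d}"
        base_symbols.append(sym)
        symbols[i] = sym
    for i in redundant:
        symbols[i] = base_symbols[rng.integers(len(base_symbols))]
    for i in unannotated:
        symbols[i] = ""
    return AnnotationTable(symbols=pd.Series(symbols, index=ids, dtype=str))


def simulate_library_counts(
    n_clusters: int,
    library_sizes: Mapping[str, int],
    pool_a: Sequence[str],
    n_enriched_clusters: int = 0,
    enrichment_ratio: float = 10.0,
    seed: int = 0,
) -> tuple[LibraryCounts, tuple[str, ...]]:
    """Multinomial sequence counts per cDNA library, with a subset of
    transcript clusters sampled ``enrichment_ratio``-fold more often in the
    pool-A libraries.

    Returns the counts table and the IDs of the truly enriched clusters.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if not set(pool_a) <= set(library_sizes):
        raise ValueError("pool_a must be a subset of the library IDs")
    if enrichment_ratio <= 0:
        raise ValueError("enrichment_ratio must be > 0")
    if not 0 <= n_enriched_clusters <= n_clusters:
        raise ValueError("n_enriched_clusters out of range")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    width = max(4, len(str(n_clusters)))
    cluster_ids = [f"CL{i:0{width}d}" for i in range(1, n_clusters + 1)]
    enriched_idx = np.sort(rng.choice(n_clusters, size=n_enriched_clusters, replace=False))
    enriched_ids = tuple(cluster_ids[i] for i in enriched_idx)

    base = np.ones(n_clusters)
    boosted = base.copy()
    boosted[enriched_idx] *= enrichment_ratio
    p_a = boosted / boosted.sum()
    p_b = base / base.sum()

    columns = {}
    for lib, size in library_sizes.items():
        if size < 0:
            raise ValueError(f"library size for {lib!r} must be >= 0")
        p = p_a if lib in set(pool_a) else p_b
        columns[lib] = rng.multinomial(size, p)
    df = pd.DataFrame(columns, index=cluster_ids, dtype=np.int64)
    return LibraryCounts(counts=df), enriched_ids


def simulate_ct_table(
    fold_changes: Mapping[str, float],
    reference_genes: Sequence[str],
    n_per_group: int = 6,
    ct_noise_sd: float = 0.25,
    seed: int = 0,
    case_label: str = "glomerulus",
    control_label: str = "tubulointerstitium",
) -> CtTable:
    """qPCR Ct measurements for a two-group design with known fold changes.

    Each gene has a control-group baseline Ct; case-group Ct is lowered by
    log2(fold) (one PCR cycle per doubling).  Reference genes are forced to
    fold 1 so normalisation cancels them exactly.
    """
    if n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    folds = {g: float(f) for g, f in fold_changes.items()}
    for ref in reference_genes:
        folds[ref] = 1.0
    if any(f <= 0 for f in folds.values()):
        raise ValueError("fold changes must be > 0")

    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(1)[0])
    genes = list(folds)
    baseline = {g: float(rng.uniform(20.0, 30.0)) for g in genes}

    rows = []
    for group, label in ((case_label, "case"), (control_label, "control")):
        for j in range(1, n_per_group + 1):
            sample_id = f"{group}_{j}"
            for g in genes:
                ct = baseline[g]
                if label == "case":
                    ct -= math.log2(folds[g])
                ct += float(rng.normal(0.0, ct_noise_sd))
                rows.append({"sample_id": sample_id, "group": group, "gene": g, "ct": ct})
    return CtTable(data=pd.DataFrame(rows))
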