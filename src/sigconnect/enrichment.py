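"""Weighted Kolmogorov-Smirnov-like enrichment score and simulation nulls.

The enrichment score (ES) of a gene set against a ranked list is the maximal
deviation of a running sum that increments at each set member ("hit") by that
gene's weight |r|^p / sum(|r|^p over hits) and decrements at every other gene
("miss") by 1/(N - N_H).  Both the hit mass and the miss mass normalise to 1,
so the running sum ends at 0 and the ES lies in [-1, 1]: close to +1 when the
set concentrates at the top of the ranking, close to -1 at the bottom.

With weight exponent p = 0 the statistic reduces to the classical (signed)
two-sample Kolmogorov-Smirnov deviation between the hit and miss rank
distributions; p = 1 (the default) weights hits by score magnitude.

Significance is assessed against a simulation null of uniformly random gene
sets of matched size drawn from the ranking's universe; the normalised
enrichment score (NES) divides the ES by the mean magnitude of same-sign null
scores, which adjusts for gene-set size.  Empirical p-values carry add-one
smoothing so they are never exactly 0; at n_perm simulations the smallest
reportable p is 1/(n_perm + 1), displayed as "<1/n_perm".
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .signatures import GeneSet, RankedList
from ._stats import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "EnrichmentConfig",
    "EnrichmentResult",
    "NullDistribution",
    "enrichment_score",
    "null_distribution",
    "sample_permutation_null",
    "normalize_es",
    "nominal_p",
    "format_p",
    "gsea_batch",
    "PrerankedGSEA",
    "GseaResults",
]


@dataclass(frozen=True)
class EnrichmentConfig:
    """Knobs of the enrichment machinery.

    weight_exponent
        p >= 0; 0 gives the classical KS statistic, 1 (default) the weighted
        form.
    n_perm
        Number of random-set simulations for null distributions (default
        10_000).
    seed
        Seed for the simulation null; identical seeds reproduce identical
        null samples.
    two_sided
        Whether CS p-values count exceedances in absolute value (default) or
        one-sided in the observed direction.
    """

    weight_exponent: float = 1.0
    n_perm: int = 10_000
    seed: int = 0
    two_sided: bool = True

    def __post_init__(self) -> None:
        if self.weight_exponent < 0:
            raise ValueError("weight_exponent must be non-negative")
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")


@dataclass
class EnrichmentResult:
    """ES of one gene set against one ranking, with optional NES/p/FDR."""

    set_name: str
    es: float
    running_sum: np.ndarray
    peak_index: int
    leading_edge: GeneSet
    size: int                      # post-intersection set size N_H
    n_dropped: int = 0             # members absent from the universe
    nes: float | None = None
    p_value: float | None = None
    fdr: float | None = None
    p_at_floor: bool = False       # no null sample was as extreme as the ES

    @property
    def p_display(self) -> str:
        if self.p_value is None:
            return "NA"
        return format_p(self.p_value, at_floor=self.p_at_floor)


@dataclass(frozen=True)
class NullDistribution:
    """ES samples of random gene sets of a fixed size against one ranking."""

    es_samples: np.ndarray
    n_perm: int
    set_size: int
    mode: str = "random-set"
    seed: int = 0

    def __post_init__(self) -> None:
        samples = np.asarray(self.es_samples, dtype=float)
        object.__setattr__(self, "es_samples", samples)
        if samples.size != self.n_perm:
            raise ValueError("es_samples length must equal n_perm")
        if samples.size and (samples.min() < -1 - 1e-12 or samples.max() > 1 + 1e-12):
            raise ValueError("null ES samples outside [-1, 1]")


def _hit_weights(scores: np.ndarray, p: float) -> np.ndarray:
    if p == 0:
        return np.ones_like(scores)
    return np.abs(scores) ** p


def _pick_extreme(hi: float, lo: float) -> float:
    # positive deviation wins exact ties: deterministic and matched between
    # the profile and positional code paths
    return hi if hi >= -lo else lo


def enrichment_score(
    ranked: RankedList,
    gene_set: GeneSet,
    config: EnrichmentConfig | None = None,
) -> EnrichmentResult:
    """Full running-sum enrichment of ``gene_set`` against ``ranked``.

    Members absent from the ranking's universe are dropped (and counted)
    before the set size N_H is fixed.  Raises if no member overlaps the
    universe or if the set covers the whole universe (the miss decrement
    would be undefined).
    """
    config = config or EnrichmentConfig()
    n = ranked.n
    positions, n_dropped = ranked.positions_of(gene_set.members)
    nh = positions.size
    if nh == 0:
        raise ValueError(
            f"no overlap between set {gene_set.name!r} and the ranking universe"
        )
    if nh >= n:
        raise ValueError(
            f"set {gene_set.name!r} covers the entire universe; "
            "miss decrement undefined"
        )
    if n_dropped:
        logger.info(
            "set %r: %d members absent from the ranking universe were dropped",
            gene_set.name, n_dropped,
        )

    w = _hit_weights(ranked.scores, config.weight_exponent)
    hit = np.zeros(n, dtype=bool)
    hit[positions] = True
    hw = np.where(hit, w, 0.0)
    total = hw.sum()
    if total == 0.0:
        # all hit scores are exactly zero: fall back to equal hit weights
        hw = hit.astype(float)
        total = float(nh)
    step = hw / total - (~hit) / (n - nh)
    running = np.cumsum(step)

    i_hi = int(np.argmax(running))
    i_lo = int(np.argmin(running))
    hi, lo = float(running[i_hi]), float(running[i_lo])
    peak = i_hi if hi >= -lo else i_lo
    es = min(1.0, max(-1.0, _pick_extreme(hi, lo)))  # guard float ulp spill

    if es >= 0:
        leading = [g for g in ranked.genes[: peak + 1] if g in gene_set]
    else:
        leading = [g for g in ranked.genes[peak:] if g in gene_set]
    return EnrichmentResult(
        set_name=gene_set.name,
        es=float(es),
        running_sum=running,
        peak_index=peak,
        leading_edge=GeneSet(f"{gene_set.name} (leading edge)", leading),
        size=int(nh),
        n_dropped=int(n_dropped),
    )


def _es_from_positions(
    positions: np.ndarray, weights: np.ndarray, n: int
) -> np.ndarray:
    """Vectorised ES for many gene sets given their sorted rank positions.

    ``positions`` is (B, k) of sorted ranks, ``weights`` the length-N hit
    weight vector |r|^p of the ranking.  Between hits the running sum only
    decreases, so its extremes occur immediately before or after a hit; only
    those 2k candidate values are evaluated per set.
    """
    b, k = positions.shape
    miss = 1.0 / (n - k)
    hw = weights[positions]                      # (B, k)
    total = hw.sum(axis=1, keepdims=True)
    zero = total[:, 0] == 0.0
    if np.any(zero):
        hw[zero] = 1.0
        total[zero] = float(k)
    cum = np.cumsum(hw, axis=1) / total          # running hit mass after hit j
    j = np.arange(k)
    misses_before = (positions - j) * miss       # miss mass before hit j
    dev_after = cum - misses_before
    dev_before = np.concatenate(
        [np.zeros((b, 1)), cum[:, :-1]], axis=1
    ) - misses_before
    hi = dev_after.max(axis=1)
    lo = dev_before.min(axis=1)
    lo = np.minimum(lo, 0.0)                     # running sum passes through 0 ends
    return np.clip(np.where(hi >= -lo, hi, lo), -1.0, 1.0)


def null_distribution(
    ranked: RankedList,
    set_size: int,
    config: EnrichmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Simulation null: ES of uniformly random sets of ``set_size`` genes.

    Sets are drawn without replacement from the ranking's universe; with a
    fixed config seed the sample sequence is reproducible.
    """
    config = config or EnrichmentConfig()
    n = ranked.n
    if not 1 <= set_size <= n - 1:
        raise ValueError(f"set_size must be in [1, {n - 1}], got {set_size}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = _hit_weights(ranked.scores, config.weight_exponent)
    positions = np.empty((config.n_perm, set_size), dtype=np.intp)
    for i in range(config.n_perm):
        positions[i] = rng.choice(n, size=set_size, replace=False)
    positions.sort(axis=1)
    samples = _es_from_positions(positions, w, n)
    return NullDistribution(
        es_samples=samples,
        n_perm=config.n_perm,
        set_size=set_size,
        mode="random-set",
        seed=config.seed,
    )


def sample_permutation_null(
    matrix,
    gene_set: GeneSet,
    config: EnrichmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> NullDistribution:
    """Phenotype-permutation null for expression-matrix inputs.

    For each permutation the lesional/non-lesional labels are swapped within
    a random subset of patient pairs (equivalently, the paired log2
    differences change sign per pair), the fold-change ranking is rebuilt
    and the gene set rescored.  Preserves gene-gene correlation, unlike the
    default random-set null; only available when sample-level data exists,
    which is why it is not the default.

    ``matrix`` is a :class:`~sigconnect.de.PairedExpressionMatrix`.
    """
    config = config or EnrichmentConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    diffs = matrix.differences()
    genes = np.asarray(diffs.index.astype(str))
    member_mask = np.isin(genes, sorted(gene_set.members))
    nh = int(member_mask.sum())
    n = genes.size
    if nh == 0:
        raise ValueError(f"no overlap between set {gene_set.name!r} and the "
                         "expression matrix features")
    if nh >= n:
        raise ValueError("set covers every feature; miss decrement undefined")
    d = diffs.to_numpy()
    samples = np.empty(config.n_perm)
    for i in range(config.n_perm):
        signs = rng.choice([-1.0, 1.0], size=d.shape[1])
        fch = (d * signs).mean(axis=1)
        order = np.lexsort((genes, -fch))
        positions = np.flatnonzero(member_mask[order])
        w = _hit_weights(fch[order], config.weight_exponent)
        samples[i] = _es_from_positions(positions[None, :], w, n)[0]
    return NullDistribution(
        es_samples=samples, n_perm=config.n_perm, set_size=nh,
        mode="sample-permutation", seed=config.seed,
    )


def normalize_es(es: float, null: NullDistribution) -> float | None:
    """NES: ES divided by the mean |ES| of same-sign null samples.

    Returns 0 for es = 0 and None (with a warning) when the null contains no
    same-sign sample.
    """
    if es == 0:
        return 0.0
    same = null.es_samples[np.sign(null.es_samples) == np.sign(es)]
    if same.size == 0:
        warnings.warn(
            "no same-sign null samples: NES undefined", RuntimeWarning,
            stacklevel=2,
        )
        return None
    return float(es / np.mean(np.abs(same)))


def _exceedances(es: float, null: NullDistribution) -> tuple[int, int]:
    """(#same-sign null samples at least as extreme as es, #same-sign)."""
    if null.es_samples.size == 0:
        raise ValueError("null distribution is empty")
    if es == 0:
        return null.es_samples.size, null.es_samples.size
    same = null.es_samples[np.sign(null.es_samples) == np.sign(es)]
    if same.size == 0:
        return 0, 0
    return int(np.sum(np.abs(same) >= abs(es))), same.size


def nominal_p(es: float, null: NullDistribution) -> float:
    """Add-one-smoothed empirical p-value of ``es`` against its null.

    p = (1 + #{same-sign null with |ES_null| >= |es|}) / (1 + #same-sign).
    Never 0; equals 1/(n_same + 1) when nothing in the null is as extreme.
    """
    k, m = _exceedances(es, null)
    if m == 0:
        return 1.0
    return (1 + k) / (1 + m)


def format_p(p: float, n_perm: int | None = None,
             at_floor: bool = False) -> str:
    """Display convention for empirical p-values: when no simulation was as
    extreme as the observation (``at_floor``, or p at/below the simulation
    resolution) the value prints as a bound, e.g. "<0.0001" at 10,000
    simulations."""
    if at_floor and n_perm is not None:
        return f"<{1.0 / n_perm:g}"
    if at_floor:
        return f"<{p:.4g}"
    if n_perm is not None and p <= 1.0 / n_perm:
        return f"<{1.0 / n_perm:g}"
    return f"{p:.4g}"


def gsea_batch(
    ranked: RankedList,
    collection: Sequence[GeneSet],
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Score a collection of gene sets against one ranking.

    Returns one row per scorable set with columns ``name, size, es, nes, p,
    fdr``, sorted by NES descending.  FDR is Benjamini-Hochberg over the
    nominal p-values within each ES sign class.  Sets with no overlap with
    the universe are skipped with a warning.  Null distributions are cached
    by post-intersection set size.
    """
    config = config or EnrichmentConfig()
    if len(collection) == 0:
        raise ValueError("empty gene-set collection")
    rng = np.random.default_rng(config.seed)
    null_cache: dict[int, NullDistribution] = {}
    rows: list[dict] = []
    results: list[EnrichmentResult] = []
    for gs in collection:
        try:
            res = enrichment_score(ranked, gs, config)
        except ValueError as exc:
            warnings.warn(f"skipping set {gs.name!r}: {exc}", RuntimeWarning,
                          stacklevel=2)
            continue
        if res.size not in null_cache:
            null_cache[res.size] = null_distribution(
                ranked, res.size, config, rng=rng
            )
        null = null_cache[res.size]
        res.nes = normalize_es(res.es, null)
        res.p_value = nominal_p(res.es, null)
        k, m = _exceedances(res.es, null)
        res.p_at_floor = (k == 0 and m > 0)
        results.append(res)
        rows.append(
            {
                "name": gs.name,
                "size": res.size,
                "es": res.es,
                "nes": res.nes,
                "p": res.p_value,
            }
        )
    if not rows:
        raise ValueError("no set in the collection overlaps the ranking")
    table = pd.DataFrame(rows)
    table["fdr"] = np.nan
    for sign_class in (table["es"] >= 0, table["es"] < 0):
        if sign_class.any():
            table.loc[sign_class, "fdr"] = bh_adjust(
                table.loc[sign_class, "p"].to_numpy()
            )
    for res, fdr in zip(results, table["fdr"]):
        res.fdr = float(fdr)
    table = table.sort_values("nes", ascending=False, ignore_index=True)
    table.attrs["results"] = results
    table.attrs["n_perm"] = config.n_perm
    return table


class GseaResults:
    """Results of a :class:`PrerankedGSEA` fit."""

    def __init__(self, model: "PrerankedGSEA", table: pd.DataFrame):
        self.model = model
        self.table = table
        self.results: list[EnrichmentResult] = table.attrs.get("results", [])

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Preranked gene-set enrichment",
            "=" * 64,
            f"ranked genes:  {self.model.ranked.n}",
            f"gene sets:     {len(self.table)} scored",
            f"weight p:      {cfg.weight_exponent:g}    "
            f"simulations: {cfg.n_perm}    seed: {cfg.seed}",
            "-" * 64,
        ]
        disp = self.table.copy()
        floors = {r.set_name: r.p_at_floor for r in self.results}
        disp["p"] = [
            format_p(v, cfg.n_perm, at_floor=floors.get(name, False))
            for name, v in zip(disp["name"], disp["p"])
        ]
        disp["fdr"] = [format_p(v, cfg.n_perm) for v in disp["fdr"]]
        lines.append(disp.to_string(index=False,
                                    float_format=lambda v: f"{v:.2f}"))
        return "\n".join(lines)


class PrerankedGSEA:
    """Preranked GSEA model: a ranking scored against a gene-set collection.

    ``PrerankedGSEA(ranked, collection).fit()`` returns a
    :class:`GseaResults` whose ``table`` mirrors the usual per-set report
    (name, size, ES, NES, p, FDR).
    """

    def __init__(
        self,
        ranked: RankedList,
        collection: Sequence[GeneSet],
        config: EnrichmentConfig | None = None,
    ):
        self.ranked = ranked
        self.collection = list(collection)
        self.config = config or EnrichmentConfig()

    def fit(self) -> GseaResults:
        return GseaResults(self, gsea_batch(self.ranked, self.collection,
                                            self.config))
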