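"""Connectivity score: one number for the agreement between a published
up/down DEG signature and a fold-change-ranked gene list.

The signature's up-set and down-set are each scored with the weighted-KS
enrichment statistic against the ranking, giving (ES_up, ES_down).  The two
are combined Connectivity-Map style:

    CS = (ES_up - ES_down) / 2   if the signs oppose (or either ES is 0),
    CS = 0                        if both ES share a sign.

CS = +1 means perfect agreement (up genes at the very top, down genes at the
very bottom), 0 no agreement, -1 perfect opposition.  Significance comes
from a simulation null: disjoint random up/down sets of matched sizes drawn
from the ranking's universe, their CS recomputed, and the observed |CS|
compared against that null with add-one smoothing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Sequence

import numpy as np
import pandas as pd

from .signatures import DEGSignature, RankedList
from .enrichment import (
    EnrichmentConfig,
    EnrichmentResult,
    enrichment_score,
    null_distribution,
    normalize_es,
    nominal_p,
    format_p,
    _es_from_positions,
    _exceedances,
    _hit_weights,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ConnectivityResult",
    "connectivity_score",
    "signature_es_pair",
    "cs_pvalue",
    "compare_studies",
    "SignatureConnectivity",
    "ConnectivityResults",
    "round_half_away",
]


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with halves away from zero (report convention), e.g.
    0.745 -> 0.75 at two decimals, where banker's rounding would give 0.74."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class ConnectivityResult:
    """(ES_up, ES_down, CS, p_CS) for one signature against one ranking."""

    study_name: str
    up: EnrichmentResult
    down: EnrichmentResult
    cs: float
    p_cs: float | None = None

    @property
    def es_up(self) -> float:
        return self.up.es

    @property
    def es_down(self) -> float:
        return self.down.es


def connectivity_score(es_up: float, es_down: float) -> float:
    """Combine a signature's two enrichment scores into one agreement value.

    (es_up - es_down)/2 when the signs oppose or either score is zero;
    0 when both share a sign ("no agreement", the Connectivity Map rule).
    """
    for name, v in (("es_up", es_up), ("es_down", es_down)):
        if not -1.0 <= v <= 1.0:
            raise ValueError(f"{name} = {v} outside [-1, 1]")
    if es_up * es_down > 0:
        return 0.0
    return (es_up - es_down) / 2.0


def signature_es_pair(
    ranked: RankedList,
    signature: DEGSignature,
    config: EnrichmentConfig | None = None,
    with_null: bool = True,
    rng: np.random.Generator | None = None,
) -> tuple[EnrichmentResult, EnrichmentResult]:
    """Enrichment of a signature's up and down sets against a ranking.

    Each direction gets its own simulation null matched to its
    post-intersection size (NES and nominal p filled in) unless
    ``with_null=False``, which returns bare ES results.
    """
    config = config or EnrichmentConfig()
    results = []
    for direction, gs in (("up", signature.up), ("down", signature.down)):
        if gs.size == 0 or not any(g in ranked for g in gs.members):
            raise ValueError(
                f"signature {signature.study_name!r}: {direction} set has no "
                "overlap with the ranking universe; connectivity undefined"
            )
        res = enrichment_score(ranked, gs, config)
        if with_null:
            null = null_distribution(ranked, res.size, config, rng=rng)
            res.nes = normalize_es(res.es, null)
            res.p_value = nominal_p(res.es, null)
            k, m = _exceedances(res.es, null)
            res.p_at_floor = (k == 0 and m > 0)
        results.append(res)
    return results[0], results[1]


def _null_cs_samples(
    ranked: RankedList,
    n_up: int,
    n_down: int,
    config: EnrichmentConfig,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """CS of disjoint random up/down sets of matched sizes (the CS null)."""
    n = ranked.n
    if n_up < 1 or n_down < 1 or n_up + n_down > n - 1:
        raise ValueError(
            f"null signature sizes ({n_up}, {n_down}) do not fit a universe "
            f"of {n} genes"
        )
    if rng is None:
        rng = np.random.default_rng(config.seed)
    w = _hit_weights(ranked.scores, config.weight_exponent)
    pos_up = np.empty((config.n_perm, n_up), dtype=np.intp)
    pos_down = np.empty((config.n_perm, n_down), dtype=np.intp)
    for i in range(config.n_perm):
        draw = rng.choice(n, size=n_up + n_down, replace=False)
        pos_up[i] = draw[:n_up]
        pos_down[i] = draw[n_up:]
    pos_up.sort(axis=1)
    pos_down.sort(axis=1)
    es_up = _es_from_positions(pos_up, w, n)
    es_down = _es_from_positions(pos_down, w, n)
    cs = np.where(es_up * es_down > 0, 0.0, (es_up - es_down) / 2.0)
    return cs


def cs_pvalue(
    ranked: RankedList,
    sizes: tuple[int, int],
    observed_cs: float,
    config: EnrichmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Simulation p-value for an observed connectivity score.

    Null signatures are disjoint random up/down sets of the given sizes.
    Two-sided by default (|CS_null| >= |CS|); one-sided (CS_null >= CS) when
    the config's ``two_sided`` flag is off.  Add-one smoothed, so the
    smallest attainable p is 1/(n_perm + 1).
    """
    config = config or EnrichmentConfig()
    null_cs = _null_cs_samples(ranked, sizes[0], sizes[1], config, rng=rng)
    if config.two_sided:
        k = int(np.sum(np.abs(null_cs) >= abs(observed_cs)))
    else:
        k = int(np.sum(null_cs >= observed_cs))
    return (1 + k) / (1 + null_cs.size)


def compare_studies(
    ranked: RankedList,
    signatures: Sequence[DEGSignature],
    config: EnrichmentConfig | None = None,
) -> pd.DataFrame:
    """Score several published DEG signatures against one ranking.

    One row per signature with the per-direction sizes, ES, NES and p plus
    the combined CS and its simulation p-value; sorted by CS descending.
    Per-signature failures (e.g. no overlap) are reported in an ``error``
    column and do not abort the batch.
    """
    config = config or EnrichmentConfig()
    if len(signatures) == 0:
        raise ValueError("no signatures supplied")
    rng = np.random.default_rng(config.seed)
    rows = []
    details: list[ConnectivityResult | None] = []
    for sig in signatures:
        row: dict = {"study": sig.study_name}
        try:
            up, down = signature_es_pair(ranked, sig, config, rng=rng)
            cs = connectivity_score(up.es, down.es)
            p_cs = cs_pvalue(ranked, (up.size, down.size), cs, config, rng=rng)
            row.update(
                n_up=up.size, n_down=down.size,
                es_up=up.es, es_down=down.es,
                nes_up=up.nes, nes_down=down.nes,
                p_up=up.p_value, p_down=down.p_value,
                cs=cs, p_cs=p_cs, error="",
            )
            details.append(ConnectivityResult(sig.study_name, up, down, cs, p_cs))
        except ValueError as exc:
            warnings.warn(f"signature {sig.study_name!r}: {exc}",
                          RuntimeWarning, stacklevel=2)
            row.update(error=str(exc))
            details.append(None)
        rows.append(row)
    table = pd.DataFrame(rows)
    if "cs" in table:
        order = table["cs"].fillna(-np.inf).argsort()[::-1].to_numpy()
        table = table.iloc[order].reset_index(drop=True)
        details = [details[i] for i in order]
    table.attrs["results"] = details
    table.attrs["n_perm"] = config.n_perm
    return table


class ConnectivityResults:
    """Fitted cross-study comparison: per-signature ES pairs and CS values."""

    def __init__(self, model: "SignatureConnectivity", table: pd.DataFrame):
        self.model = model
        self.table = table
        self.results = [r for r in table.attrs.get("results", []) if r is not None]

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Signature connectivity vs ranked list",
            "=" * 72,
            f"ranked genes: {self.model.ranked.n}    "
            f"simulations: {cfg.n_perm}    seed: {cfg.seed}",
            "-" * 72,
            f"{'study':<24}{'size':>11}{'ES up':>8}{'ES down':>9}"
            f"{'CS':>7}{'p(CS)':>10}",
        ]
        for _, r in self.table.iterrows():
            if r.get("error"):
                lines.append(f"{r['study']:<24}  failed: {r['error']}")
                continue
            lines.append(
                f"{r['study']:<24}{int(r['n_up']):>5}/{int(r['n_down']):<5}"
                f"{r['es_up']:>8.2f}{r['es_down']:>9.2f}"
                f"{round_half_away(r['cs']):>7.2f}"
                f"{format_p(r['p_cs'], cfg.n_perm):>10}"
            )
        return "\n".join(lines)


class SignatureConnectivity:
    """Model object: a ranking compared against published DEG signatures.

    ``SignatureConnectivity(ranked, signatures).fit()`` returns
    :class:`ConnectivityResults` carrying the per-signature enrichment
    scores, connectivity scores, simulation p-values and a printable
    ``summary()``.
    """

    def __init__(
        self,
        ranked: RankedList,
        signatures: Sequence[DEGSignature],
        config: EnrichmentConfig | None = None,
    ):
        self.ranked = ranked
        self.signatures = list(signatures)
        self.config = config or EnrichmentConfig()

    def fit(self) -> ConnectivityResults:
        return ConnectivityResults(
            self, compare_studies(self.ranked, self.signatures, self.config)
        )
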