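"""Paired differential expression: from a log2 expression matrix with a
lesional/non-lesional pairing to fold changes, (moderated) paired t-tests,
BH-adjusted FDR, DEG selection and the fold-change ranking.

The design is within-patient: each patient contributes one lesional and one
non-lesional sample, and all statistics operate on the per-patient log2
differences.  The moderated test shrinks each feature's difference variance
toward a prior estimated across features (empirical Bayes, moment matching
on the log variances), which stabilises t-statistics when the number of
pairs is small.

DEG selection follows the conventional cut-offs: FDR < 0.05 and linear fold
change strictly greater than 2 (|log2 FCH| > 1); boundary features are
excluded.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import bh_adjust, estimate_variance_prior
from .signatures import DEGSignature, GeneSet, RankedList, build_ranked_list

logger = logging.getLogger(__name__)

__all__ = [
    "PairedExpressionMatrix",
    "ModerationParams",
    "paired_log2_fch",
    "moderated_paired_t",
    "select_deg",
    "low_intensity_fraction",
    "expression_filter",
    "log2fch_to_linear",
    "PairedDifferentialExpression",
    "DEResults",
]

LOW_INTENSITY_THRESHOLD = 4.0  # log2 units below which array FCH is unreliable


@dataclass(frozen=True)
class ModerationParams:
    """Empirical-Bayes prior for variance shrinkage.

    prior_df
        d0, prior degrees of freedom (may be inf: complete shrinkage).
    prior_var
        s0^2, prior variance of the per-pair log2 differences.
    """

    prior_df: float
    prior_var: float

    def __post_init__(self) -> None:
        if self.prior_df < 0:
            raise ValueError("prior_df must be >= 0")
        if self.prior_var <= 0:
            raise ValueError("prior_var must be positive")


class PairedExpressionMatrix:
    """Log2 expression (features x samples) with a paired sample design.

    Parameters
    ----------
    values
        DataFrame indexed by feature (probeset or gene), columns = sample
        ids, entries = finite log2 expression values.
    pairs
        Sequence of ``(patient_id, lesional_sample, non_lesional_sample)``.
        Every sample column must appear in exactly one pair slot.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        pairs: Sequence[tuple[str, str, str]],
    ):
        if len(pairs) < 2:
            raise ValueError("need at least 2 patient pairs")
        seen: set[str] = set()
        for patient, les, non in pairs:
            for s in (les, non):
                if s not in values.columns:
                    raise ValueError(
                        f"patient {patient!r}: sample {s!r} missing from matrix"
                    )
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} appears in more than one pair slot"
                    )
                seen.add(s)
        extra = set(values.columns) - seen
        if extra:
            raise ValueError(
                f"samples not assigned to any pair: {sorted(extra)[:5]}"
            )
        vals = values.astype(float)
        if not np.all(np.isfinite(vals.to_numpy())):
            raise ValueError("expression values must be finite")
        if vals.index.duplicated().any():
            raise ValueError("duplicate feature identifiers")
        self.values = vals
        self.pairs = [tuple(p) for p in pairs]

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def features(self) -> pd.Index:
        return self.values.index

    @property
    def n_features(self) -> int:
        return len(self.values)

    def differences(self) -> pd.DataFrame:
        """Per-patient lesional minus non-lesional log2 differences."""
        cols = {}
        for patient, les, non in self.pairs:
            cols[patient] = self.values[les] - self.values[non]
        return pd.DataFrame(cols, index=self.values.index)

    def subset(self, features: Sequence[str]) -> "PairedExpressionMatrix":
        return PairedExpressionMatrix(self.values.loc[list(features)], self.pairs)


def paired_log2_fch(matrix: PairedExpressionMatrix) -> pd.Series:
    """Mean within-pair (lesional - non-lesional) log2 difference per feature."""
    return matrix.differences().mean(axis=1).rename("log2_fch")


def moderated_paired_t(
    matrix: PairedExpressionMatrix,
    moderation: bool = True,
    prior: ModerationParams | None = None,
) -> pd.DataFrame:
    """Paired t-test per feature, optionally variance-moderated.

    With ``moderation=False`` this is the classical paired t with
    df = n_pairs - 1.  With moderation, each feature's difference variance is
    shrunk toward an across-feature prior,

        s~^2_g = (d0 s0^2 + d_g s^2_g) / (d0 + d_g),   d_g = n_pairs - 1,

    the t-statistic uses s~_g and the reference distribution gains the prior
    degrees of freedom (df = d0 + d_g).  (d0, s0^2) are estimated by moment
    matching on the log sample variances unless supplied via ``prior``; if
    the estimate is non-finite the test falls back to unmoderated with a
    warning.  Two-sided p-values.
    """
    diffs = matrix.differences().to_numpy()
    n = matrix.n_pairs
    d_g = n - 1
    mean = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)

    if moderation:
        if prior is None:
            try:
                d0, s0sq = estimate_variance_prior(s2, d_g)
            except (ValueError, FloatingPointError) as exc:
                if np.all(s2 == 0):
                    raise ValueError(
                        "all features have zero variance; cannot test"
                    ) from exc
                warnings.warn(
                    f"variance-prior estimation failed ({exc}); falling back "
                    "to the unmoderated paired t-test", RuntimeWarning,
                    stacklevel=2,
                )
                return moderated_paired_t(matrix, moderation=False)
        else:
            d0, s0sq = prior.prior_df, prior.prior_var
        if np.isinf(d0):
            s2_tilde = np.full_like(s2, s0sq)
            df_total = np.inf
        else:
            s2_tilde = (d0 * s0sq + d_g * s2) / (d0 + d_g)
            df_total = d0 + d_g
    else:
        if np.all(s2 == 0):
            raise ValueError("all features have zero variance; cannot test")
        s2_tilde = s2
        df_total = float(d_g)
        d0, s0sq = 0.0, np.nan

    se = np.sqrt(s2_tilde / n)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, mean / np.where(se > 0, se, 1.0), np.sign(mean) * np.inf)
    t = np.where((se == 0) & (mean == 0), 0.0, t)
    df_for_p = 1e9 if np.isinf(df_total) else df_total
    p = 2.0 * sps.t.sf(np.minimum(np.abs(t), 1e15), df_for_p)
    p = np.maximum(p, np.finfo(float).tiny)  # floor at numerical minimum
    out = pd.DataFrame(
        {"t": t, "df": df_total, "p": p}, index=matrix.features
    )
    out.attrs["prior_df"] = d0
    out.attrs["prior_var"] = s0sq
    out.attrs["moderation"] = bool(moderation)
    return out


def select_deg(
    stats: pd.DataFrame,
    study_name: str = "study",
    fch_threshold: float = 2.0,
    fdr_threshold: float = 0.05,
) -> DEGSignature:
    """DEG selection at FDR < ``fdr_threshold`` and linear fold change
    strictly greater than ``fch_threshold``.

    ``stats`` needs columns ``log2_fch`` and ``fdr``.  "More than 2 fold" is
    read strictly: |log2 FCH| > log2(fch_threshold), boundary excluded.
    """
    if len(stats) == 0:
        raise ValueError("empty statistics table")
    log2_cut = np.log2(fch_threshold)
    sig = stats["fdr"] < fdr_threshold
    up = stats.index[sig & (stats["log2_fch"] > log2_cut)]
    down = stats.index[sig & (stats["log2_fch"] < -log2_cut)]
    if len(up) == 0 and len(down) == 0:
        warnings.warn(
            f"no features pass FDR<{fdr_threshold} and FCH>{fch_threshold}",
            RuntimeWarning, stacklevel=2,
        )
    return DEGSignature(
        study_name=study_name,
        up=GeneSet(f"{study_name} - UP", up),
        down=GeneSet(f"{study_name} - Down", down),
    )


def low_intensity_fraction(
    matrix: PairedExpressionMatrix | pd.DataFrame,
    threshold: float = LOW_INTENSITY_THRESHOLD,
) -> pd.Series:
    """Percent of samples per feature with log2 expression below ``threshold``.

    Features that are low in most samples have unreliable array fold
    changes (the motivation for RT-PCR confirmation of low-abundance
    cytokines)."""
    values = matrix.values if isinstance(matrix, PairedExpressionMatrix) else matrix
    frac = (values < threshold).mean(axis=1) * 100.0
    return frac.rename("low_intensity_pct")


def expression_filter(
    matrix: PairedExpressionMatrix,
    min_expr: float = LOW_INTENSITY_THRESHOLD,
    max_low_fraction: float = 0.9,
    min_variance: float = 1e-3,
) -> tuple[PairedExpressionMatrix, dict]:
    """Drop features with unreliably low expression or negligible variability.

    A feature is removed when its log2 expression is below ``min_expr`` in at
    least ``max_low_fraction`` of the samples, or when its across-sample
    variance is below ``min_variance``.  Permissive defaults; the filter
    report says what was removed and why.
    """
    values = matrix.values
    low_frac = (values < min_expr).mean(axis=1)
    variance = values.var(axis=1, ddof=1)
    low_mask = low_frac >= max_low_fraction if max_low_fraction > 0 else (
        pd.Series(False, index=values.index)
    )
    var_mask = variance < min_variance
    drop = low_mask | var_mask
    if drop.all():
        raise ValueError("expression filter removed every feature")
    report = {
        "n_input": int(len(values)),
        "n_removed_low": int(low_mask.sum()),
        "n_removed_variance": int((var_mask & ~low_mask).sum()),
        "n_kept": int((~drop).sum()),
        "min_expr": min_expr,
        "max_low_fraction": max_low_fraction,
        "min_variance": min_variance,
    }
    logger.info("expression_filter: %s", report)
    kept = matrix.subset(values.index[~drop])
    return kept, report


def log2fch_to_linear(x):
    """Linear fold change 2**x from a log2 fold change."""
    return np.power(2.0, x)


class DEResults:
    """Fitted paired DE analysis: per-feature statistics and derived objects.

    Attributes
    ----------
    table
        DataFrame per feature: ``log2_fch, t, df, p, fdr,
        low_intensity_pct``.
    prior
        :class:`ModerationParams` actually used (None when unmoderated).
    filter_report
        Dict from :func:`expression_filter`, or None if filtering was off.
    """

    def __init__(
        self,
        model: "PairedDifferentialExpression",
        table: pd.DataFrame,
        prior: ModerationParams | None,
        filter_report: dict | None,
    ):
        self.model = model
        self.table = table
        self.prior = prior
        self.filter_report = filter_report

    def ranked_list(self) -> RankedList:
        """Fold-change ranking over all analysed features (ties broken
        lexicographically)."""
        return build_ranked_list(self.table["log2_fch"].to_dict())

    def signature(
        self,
        study_name: str | None = None,
        fch_threshold: float = 2.0,
        fdr_threshold: float = 0.05,
    ) -> DEGSignature:
        return select_deg(
            self.table,
            study_name=study_name or self.model.study_name,
            fch_threshold=fch_threshold,
            fdr_threshold=fdr_threshold,
        )

    def summary(self) -> str:
        sig = self.table[(self.table["fdr"] < 0.05)]
        n_up = int((sig["log2_fch"] > 1).sum())
        n_down = int((sig["log2_fch"] < -1).sum())
        lines = [
            f"Paired differential expression: {self.model.study_name}",
            "=" * 64,
            f"features analysed:   {len(self.table)}",
            f"patient pairs:       {self.model.matrix.n_pairs}",
        ]
        if self.filter_report:
            fr = self.filter_report
            lines.append(
                f"filtered out:        {fr['n_removed_low']} low-expression, "
                f"{fr['n_removed_variance']} low-variance "
                f"(of {fr['n_input']})"
            )
        if self.prior is not None:
            d0 = self.prior.prior_df
            lines.append(
                f"moderation prior:    d0 = {d0:.3g}, "
                f"s0^2 = {self.prior.prior_var:.4g}"
            )
        else:
            lines.append("moderation:          off (classical paired t)")
        lines += [
            f"DEG (FDR<0.05, FCH>2): {n_up} up, {n_down} down",
            "-" * 64,
            "top by |log2 FCH|:",
            self.table.reindex(
                self.table["log2_fch"].abs().sort_values(ascending=False).index
            ).head(10).to_string(float_format=lambda v: f"{v:.3g}"),
        ]
        return "\n".join(lines)


class PairedDifferentialExpression:
    """Model: paired lesional vs non-lesional differential expression.

    ``PairedDifferentialExpression(values, pairs).fit()`` filters features,
    computes fold changes, (moderated) paired t-statistics and BH FDR, and
    returns a :class:`DEResults` from which the fold-change ranking and the
    DEG signature are derived.
    """

    def __init__(
        self,
        values: pd.DataFrame | PairedExpressionMatrix,
        pairs: Sequence[tuple[str, str, str]] | None = None,
        study_name: str = "study",
    ):
        if isinstance(values, PairedExpressionMatrix):
            self.matrix = values
        else:
            if pairs is None:
                raise ValueError("pairs required when passing a raw DataFrame")
            self.matrix = PairedExpressionMatrix(values, pairs)
        self.study_name = study_name

    def fit(
        self,
        moderation: bool = True,
        prior: ModerationParams | None = None,
        filter_features: bool = True,
        filter_params: dict | None = None,
    ) -> DEResults:
        matrix = self.matrix
        report = None
        if filter_features:
            matrix, report = expression_filter(matrix, **(filter_params or {}))
        fch = paired_log2_fch(matrix)
        tt = moderated_paired_t(matrix, moderation=moderation, prior=prior)
        table = pd.DataFrame(
            {
                "log2_fch": fch,
                "t": tt["t"],
                "df": tt["df"],
                "p": tt["p"],
                "fdr": bh_adjust(tt["p"].to_numpy()),
                "low_intensity_pct": low_intensity_fraction(matrix),
            }
        )
        used_prior = None
        if tt.attrs.get("moderation"):
            used_prior = ModerationParams(
                prior_df=tt.attrs["prior_df"], prior_var=tt.attrs["prior_var"]
            )
        return DEResults(self, table, used_prior, report)
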