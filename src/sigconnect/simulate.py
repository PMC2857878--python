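"""Synthetic two-study generator with a planted shared disease signature.

Emulates the statistical structure of paired lesional/non-lesional skin
expression studies run in two labs on two overlapping array platforms:

* a gene universe split into a core measured by both platforms and a private
  block per platform (``platform_shared_fraction`` is the fraction of each
  platform's genes that the platforms share);
* a planted disease signature of up- and down-regulated genes with a common
  nominal log2 effect, jittered independently per study to model laboratory,
  protocol and platform differences;
* Gaussian log2-scale noise per sample, with the lesional value of a pair
  built from its non-lesional value plus the study's realised effect plus
  pair-level noise;
* a slice of genes with baselines near the low-intensity threshold (4 log2
  units), where array fold changes are unreliable.

Every draw is reproducible from the config seed.  The generator exists so
that the full pipeline — DE statistics, DEG selection, fold-change ranking,
signature enrichment, connectivity scores, Venn overlap — is exercisable
end-to-end, and so the central qualitative claim (two studies can share a
strong signature yet overlap modestly in their DEG lists) is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .de import PairedExpressionMatrix
from .signatures import DEGSignature, GeneSet

__all__ = ["SimulationConfig", "SyntheticTruth", "simulate_two_studies",
           "random_signature"]

LOW_THRESHOLD = 4.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the two-study simulation.

    Defaults mirror a pair of moderately sized paired-design microarray
    studies: 5000 genes, 300 up / 300 down signature genes with a nominal
    +/-2 log2 effect, between-study effect jitter 0.5, unit log2 noise,
    15 and 16 patient pairs, platforms sharing 80% of their content, and 10%
    of genes expressed near the 4.0 low-intensity threshold.
    """

    n_genes: int = 5000
    n_signature_up: int = 300
    n_signature_down: int = 300
    effect_log2: float = 2.0
    effect_sd_between_studies: float = 0.5
    noise_sd: float = 1.0
    n_pairs_study_a: int = 15
    n_pairs_study_b: int = 16
    platform_shared_fraction: float = 0.8
    baseline_mean: float = 7.0
    baseline_sd: float = 1.5
    low_expression_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if max(self.n_signature_up, self.n_signature_down) >= self.n_genes / 2:
            raise ValueError("each signature side must be < n_genes/2")
        if not 0 < self.platform_shared_fraction <= 1:
            raise ValueError("platform_shared_fraction must be in (0, 1]")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if self.effect_log2 < 0:
            raise ValueError("effect_log2 must be >= 0 (0 = pure-noise null)")
        if self.effect_sd_between_studies < 0:
            raise ValueError("effect_sd_between_studies must be >= 0")
        if min(self.n_pairs_study_a, self.n_pairs_study_b) < 2:
            raise ValueError("each study needs at least 2 pairs")
        if not 0 <= self.low_expression_fraction <= 1:
            raise ValueError("low_expression_fraction must be in [0, 1]")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted signature and the per-study realised effects."""

    true_up: GeneSet
    true_down: GeneSet
    effects_a: dict[str, float] = field(repr=False, default_factory=dict)
    effects_b: dict[str, float] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        if self.true_up.members & self.true_down.members:
            raise ValueError("true up and down sets overlap")


def _platform_split(genes: np.ndarray, f: float,
                    rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Split the universe into two platforms sharing fraction f of their
    content: shared core of n*f/(2-f) genes plus two private blocks."""
    n = genes.size
    shuffled = genes[rng.permutation(n)]
    n_private = int(round(n * (1 - f) / (2 - f)))
    n_shared = n - 2 * n_private
    shared = shuffled[:n_shared]
    priv_a = shuffled[n_shared:n_shared + n_private]
    priv_b = shuffled[n_shared + n_private:]
    return np.concatenate([shared, priv_a]), np.concatenate([shared, priv_b])


def _study_matrix(
    study: str,
    platform: np.ndarray,
    baselines: pd.Series,
    effects: dict[str, float],
    n_pairs: int,
    noise_sd: float,
    rng: np.random.Generator,
) -> PairedExpressionMatrix:
    genes = np.sort(platform)
    base = baselines.loc[genes].to_numpy()[:, None]
    delta = np.array([effects.get(g, 0.0) for g in genes])[:, None]
    non_lesional = base + rng.normal(0.0, noise_sd, size=(genes.size, n_pairs))
    lesional = non_lesional + delta + rng.normal(
        0.0, noise_sd, size=(genes.size, n_pairs)
    )
    pairs = []
    cols = {}
    for i in range(n_pairs):
        patient = f"{study}_p{i + 1:02d}"
        cols[f"{patient}_LS"] = lesional[:, i]
        cols[f"{patient}_NL"] = non_lesional[:, i]
        pairs.append((patient, f"{patient}_LS", f"{patient}_NL"))
    values = pd.DataFrame(cols, index=genes)
    return PairedExpressionMatrix(values, pairs)


def simulate_two_studies(
    config: SimulationConfig | None = None,
) -> tuple[PairedExpressionMatrix, PairedExpressionMatrix, SyntheticTruth]:
    """Draw paired expression matrices for two studies of one disease.

    Returns the two studies' matrices (each restricted to its platform's
    genes) and the planted truth.  Deterministic given ``config.seed``.
    """
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.seed)
    genes = np.array([f"g{i:05d}" for i in range(config.n_genes)])

    # baselines: bulk of genes around baseline_mean, a slice near the
    # low-intensity threshold where array fold changes are unreliable
    baselines = rng.normal(config.baseline_mean, config.baseline_sd,
                           size=config.n_genes)
    n_low = int(round(config.low_expression_fraction * config.n_genes))
    low_idx = rng.choice(config.n_genes, size=n_low, replace=False)
    baselines[low_idx] = rng.normal(LOW_THRESHOLD, 0.5, size=n_low)
    baselines = pd.Series(baselines, index=genes)

    platform_a, platform_b = _platform_split(
        genes, config.platform_shared_fraction, rng
    )

    sig_genes = rng.choice(
        genes, size=config.n_signature_up + config.n_signature_down,
        replace=False,
    )
    true_up = sig_genes[: config.n_signature_up]
    true_down = sig_genes[config.n_signature_up:]
    signs = dict({g: +1.0 for g in true_up}, **{g: -1.0 for g in true_down})

    effects = {}
    for study, platform in (("A", platform_a), ("B", platform_b)):
        on_platform = [g for g in sig_genes if g in set(platform)]
        jitter = rng.normal(0.0, config.effect_sd_between_studies,
                            size=len(on_platform))
        effects[study] = {
            g: signs[g] * config.effect_log2 + j
            for g, j in zip(on_platform, jitter)
        }

    mat_a = _study_matrix("A", platform_a, baselines, effects["A"],
                          config.n_pairs_study_a, config.noise_sd, rng)
    mat_b = _study_matrix("B", platform_b, baselines, effects["B"],
                          config.n_pairs_study_b, config.noise_sd, rng)
    truth = SyntheticTruth(
        true_up=GeneSet("true - UP", true_up),
        true_down=GeneSet("true - Down", true_down),
        effects_a=effects["A"],
        effects_b=effects["B"],
    )
    return mat_a, mat_b, truth


def random_signature(
    universe: Iterable[str],
    n_up: int,
    n_down: int,
    seed: int | np.random.Generator = 0,
    study_name: str = "random",
) -> DEGSignature:
    """Disjoint uniform random up/down sets from a gene universe."""
    genes = np.array(sorted(set(map(str, universe))))
    if n_up + n_down > genes.size:
        raise ValueError(
            f"requested {n_up}+{n_down} genes from a universe of {genes.size}"
        )
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    draw = rng.choice(genes, size=n_up + n_down, replace=False)
    return DEGSignature(
        study_name=study_name,
        up=GeneSet(f"{study_name} - UP", draw[:n_up]),
        down=GeneSet(f"{study_name} - Down", draw[n_up:]),
    )
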