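"""Generative simulator for single-gene and pair RPol II profiles.

Draws hidden promoter parameters from their gamma hyperpriors, builds the
expected exponential-decay curves, and emits Poisson counts per 20-bp
bin — the generative reading of the promoter model.  "Unexpressed" genes
are simulated with no TSS enrichment (S = T = B, a flat background
profile); a low-enrichment variant (S = 2B) is available since real
unexpressed genes show markedly reduced rather than absent RPol II.

Default hyperprior means (B, T, S, Kp, Kt) = (2, 6, 80, 200 bp, 400 bp)
with shape 4 are fixture values chosen to resemble typical TSS metagene
profiles; they are a simulation convention, not measured quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .model import (
    Hyperparams,
    PairParams,
    SinglePromoterParams,
    expected_lambda_single,
    pair_lambda_profile,
)
from .profiles import BinnedProfile, pair_geometry, single_gene_geometry

logger = logging.getLogger(__name__)

__all__ = [
    "SimConfig",
    "Cohort",
    "PairRecord",
    "default_theta",
    "sample_params",
    "sample_pair_params",
    "simulate_profile",
    "simulate_single_profile",
    "simulate_pair_from_params",
    "simulate_cohort",
]

DEFAULT_MEANS = {"B": 2.0, "T": 6.0, "S": 80.0, "Kp": 200.0, "Kt": 400.0}


def default_theta(shape: float = 4.0, means: dict | None = None) -> Hyperparams:
    """Fixture hyperpriors (see module docstring); gamma scale = mean/shape."""
    return Hyperparams.from_moments(means or DEFAULT_MEANS, shape=shape)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated cohort.

    ``n_genes`` isolated single-gene profiles feed hyperparameter
    estimation; ``n_pairs`` divergent-pair profiles carry ground-truth
    bi-peak / single labels, with ``unexpressed_fraction`` of the pairs
    having one unexpressed gene (a true single peak).
    """

    seed: int
    theta: Hyperparams = field(default_factory=default_theta)
    flank: int = 2000
    bin_size: int = 20
    n_genes: int = 200
    n_pairs: int = 100
    distance_range: tuple[int, int] = (0, 1000)
    unexpressed_fraction: float = 0.5
    unexpressed_mode: str = "flat"  # 'flat' (S = B) or 'low' (S = 2B)
    noise: bool = True

    def __post_init__(self) -> None:
        if self.flank % self.bin_size != 0:
            raise ValueError("flank must be divisible by bin_size")
        if not 0.0 <= self.unexpressed_fraction <= 1.0:
            raise ValueError("unexpressed_fraction must be in [0, 1]")
        if self.unexpressed_mode not in ("flat", "low"):
            raise ValueError("unexpressed_mode must be 'flat' or 'low'")


def sample_params(
    theta: Hyperparams,
    rng: np.random.Generator | int,
    unexpressed: bool = False,
    unexpressed_mode: str = "flat",
    min_enrichment: float | None = None,
    max_tries: int = 1000,
) -> SinglePromoterParams:
    """Draw one promoter's parameters from the gamma hyperpriors.

    Expressed draws violating the peak ordering S >= max(B, T) are
    rejected and redrawn (logged); an excessive rejection rate means the
    hyperpriors contradict the ordering and raises.  ``min_enrichment``
    additionally conditions expressed draws on S >= min_enrichment * B,
    the way a strongly-expressed cohort is specified.  Unexpressed genes
    replace the TSS enrichment: S = T = B ('flat') or S = 2B, T = B
    ('low').
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    rejected = 0
    for _ in range(max_tries):
        vals = {
            name: rng.gamma(theta.family(name).alpha, theta.family(name).beta)
            for name in ("B", "T", "S", "Kp", "Kt")
        }
        if unexpressed:
            b = vals["B"]
            vals["T"] = b
            vals["S"] = b if unexpressed_mode == "flat" else 2 * b
            return SinglePromoterParams(**vals)
        if min_enrichment is not None and vals["S"] < min_enrichment * vals["B"]:
            rejected += 1
            continue
        if vals["S"] >= max(vals["B"], vals["T"]):
            if rejected:
                logger.debug("rejected %d draws violating S >= max(B, T)", rejected)
            return SinglePromoterParams(**vals)
        rejected += 1
    raise ValueError(
        f"hyperpriors inconsistent with S >= max(B, T): {rejected}/{max_tries} "
        "draws rejected"
    )


def sample_pair_params(theta: Hyperparams, rng, unexpressed_gene: int | None = None,
                       unexpressed_mode: str = "flat") -> PairParams:
    """Draw both genes' parameters; ``unexpressed_gene`` in {None, 1, 2}."""
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    g1 = sample_params(theta, rng, unexpressed=unexpressed_gene == 1,
                       unexpressed_mode=unexpressed_mode)
    g2 = sample_params(theta, rng, unexpressed=unexpressed_gene == 2,
                       unexpressed_mode=unexpressed_mode)
    return PairParams(gene1=g1, gene2=g2)


def simulate_profile(Y, geometry: BinnedProfile, rng, noise: bool = True) -> BinnedProfile:
    """Poisson counts over a geometry from pair or single parameters.

    With ``noise=False`` counts are the rounded expected curve.
    """
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    if isinstance(Y, PairParams):
        lam = pair_lambda_profile(Y, geometry)
    elif isinstance(Y, SinglePromoterParams):
        if geometry.tss_bins is None:
            raise ValueError("single-gene geometry needs a TSS bin")
        i_tss = geometry.tss_bins[0]
        idx = np.arange(geometry.n_bins)
        D = np.abs(idx - i_tss) * float(geometry.bin_size)
        lam = np.where(idx < i_tss,
                       expected_lambda_single(Y, D, "promoter"),
                       expected_lambda_single(Y, D, "transcript"))
    else:
        raise TypeError("Y must be PairParams or SinglePromoterParams")
    counts = rng.poisson(lam) if noise else np.rint(lam).astype(np.int64)
    return geometry.with_counts(counts)


def simulate_single_profile(params: SinglePromoterParams, flank: int = 2000,
                            bin_size: int = 20, rng=0, noise: bool = True) -> BinnedProfile:
    """TSS-centred plus-strand-oriented single-gene profile."""
    return simulate_profile(params, single_gene_geometry(flank, bin_size), rng, noise)


def simulate_pair_from_params(Y: PairParams, distance: int, flank: int = 2000,
                              bin_size: int = 20, rng=0, noise: bool = True) -> BinnedProfile:
    """Labelled divergent-pair profile at the given inter-TSS distance."""
    return simulate_profile(Y, pair_geometry(distance, flank, bin_size), rng, noise)


@dataclass(frozen=True)
class PairRecord:
    profile: BinnedProfile
    params: PairParams
    label: str  # 'bipeak_true' | 'single_true'
    distance: int
    unexpressed_gene: int | None


@dataclass(frozen=True)
class Cohort:
    """Simulated dataset with full ground truth."""

    singles: list  # of (BinnedProfile, SinglePromoterParams)
    pairs: list  # of PairRecord
    config: SimConfig


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate singles and labelled pair profiles under ``cfg``.

    Exactly ``round(unexpressed_fraction * n_pairs)`` pairs are true
    single peaks (one gene unexpressed, the side alternating by draw);
    distances are uniform over ``distance_range`` rounded down to bin
    multiples.  Fully deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    singles = []
    for _ in range(cfg.n_genes):
        p = sample_params(cfg.theta, rng)
        singles.append((simulate_single_profile(p, cfg.flank, cfg.bin_size,
                                                rng, cfg.noise), p))

    n_single_true = int(round(cfg.unexpressed_fraction * cfg.n_pairs))
    flags = np.zeros(cfg.n_pairs, dtype=bool)
    flags[:n_single_true] = True
    rng.shuffle(flags)

    lo, hi = cfg.distance_range
    pairs = []
    for k in range(cfg.n_pairs):
        if flags[k]:
            unexpressed = int(rng.integers(1, 3))
        else:
            unexpressed = None
        Y = sample_pair_params(cfg.theta, rng, unexpressed_gene=unexpressed,
                               unexpressed_mode=cfg.unexpressed_mode)
        distance = int(rng.integers(lo, max(hi, lo + 1)))
        distance = (distance // cfg.bin_size) * cfg.bin_size
        prof = simulate_pair_from_params(Y, distance, cfg.flank, cfg.bin_size,
                                         rng, cfg.noise)
        pairs.append(PairRecord(
            profile=prof, params=Y,
            label="single_true" if flags[k] else "bipeak_true",
            distance=distance, unexpressed_gene=unexpressed,
        ))
    return Cohort(singles=singles, pairs=pairs, config=cfg)
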