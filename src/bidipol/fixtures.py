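"""A small deterministic toy set of hand-constructed pair profiles.

Twelve noise-free divergent-pair windows built directly from the
expected-count curves (counts are rounded expectations, so the set is
identical on every platform): four clear bi-peaks, three left-only
promoters, three right-only promoters, and two broad central peaks
covering both TSSs.  Used as a fixed classification fixture.
"""

from __future__ import annotations

import numpy as np

from .model import PairParams, SinglePromoterParams, pair_lambda_profile
from .profiles import BinnedProfile, pair_geometry

__all__ = ["toy_pair_profiles"]

_EXPR = dict(B=2.0, T=6.0, S=80.0, Kp=150.0, Kt=300.0)
_FLAT = dict(B=2.0, T=2.0, S=2.0, Kp=150.0, Kt=300.0)


def _pair(g1: dict, g2: dict) -> PairParams:
    return PairParams(gene1=SinglePromoterParams(**g1),
                      gene2=SinglePromoterParams(**g2))


def _noise_free(Y: PairParams, distance: int, flank: int = 2000,
                bin_size: int = 20) -> BinnedProfile:
    geom = pair_geometry(distance, flank=flank, bin_size=bin_size)
    lam = pair_lambda_profile(Y, geom)
    return geom.with_counts(np.rint(lam).astype(np.int64))


def _centre(distance: int, flank: int = 2000, bin_size: int = 20,
            B: float = 2.0, S: float = 60.0, K: float = 400.0) -> BinnedProfile:
    """One broad peak at the pair midpoint, covering both TSSs."""
    geom = pair_geometry(distance, flank=flank, bin_size=bin_size)
    i_neg, i_pos = geom.tss_bins
    i_mid = (i_neg + i_pos) / 2.0
    d = np.abs(np.arange(geom.n_bins) - i_mid) * bin_size
    lam = B + (S - B) * np.exp(-d / K)
    return geom.with_counts(np.rint(lam).astype(np.int64))


def toy_pair_profiles():
    """Return the twelve (profile, design_label) toy cases.

    ``design_label`` is the promoter category each case was constructed
    to represent: 'double', 'left', 'right' or 'centre'.
    """
    cases = []
    for dist in (600, 700, 800, 640):
        cases.append((_noise_free(_pair(_EXPR, _EXPR), dist), "double"))
    for dist in (800, 760, 900):  # only the minus-strand (left) gene bound
        cases.append((_noise_free(_pair(_FLAT, _EXPR), dist), "left"))
    for dist in (800, 840, 720):  # only the plus-strand (right) gene bound
        cases.append((_noise_free(_pair(_EXPR, _FLAT), dist), "right"))
    for dist in (200, 160):
        cases.append((_centre(dist), "centre"))
    return cases
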