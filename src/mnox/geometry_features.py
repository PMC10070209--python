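"""Octahedral geometry: antipodal ligand pairing and the (E, A) features.

E is the mean of the four equatorial Mn–ligand distances and A the mean of
the two axial ones; for d4 Mn(III) the Jahn–Teller effect elongates the
axial pair, which is what makes the pair separable from bond lengths alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .structure_io import MnSite

logger = logging.getLogger(__name__)

def _enumerate_matchings() -> list[tuple[tuple[int, int], ...]]:
    """All 15 perfect matchings of 6 items into 3 unordered pairs."""
    out = []
    items = list(range(6))
    first = items[0]
    for partner in items[1:]:
        rest = [i for i in items[1:] if i != partner]
        for second_partner in rest[1:]:
            pair2 = (rest[0], second_partner)
            pair3 = tuple(i for i in rest if i not in pair2)
            out.append(((first, partner), tuple(sorted(pair2)), tuple(sorted(pair3))))
    return out


_MATCHINGS = tuple(_enumerate_matchings())
assert len(_MATCHINGS) == 15


class GeometryError(ValueError):
    """Contract violation in octahedral feature extraction."""


@dataclass
class OctahedralFeatures:
    """The two classifier features of one octahedral Mn site (Å)."""

    E: float
    A: float
    pairing: tuple[tuple[int, int], ...]
    axial_pair_index: int

    @property
    def axial_pair(self) -> tuple[int, int]:
        return self.pairing[self.axial_pair_index]

    @property
    def equatorial_indices(self) -> tuple[int, ...]:
        ax = set(self.axial_pair)
        return tuple(i for i in range(6) if i not in ax)

    def as_array(self) -> np.ndarray:
        return np.array([self.E, self.A], dtype=float)


def ligand_angle(site: MnSite, i: int, j: int) -> float:
    """Angle ligand_i–Mn–ligand_j in degrees."""
    u = site.ligands[i].coord - site.mn_coord
    v = site.ligands[j].coord - site.mn_coord
    cosang = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def pairing_cost(site: MnSite, matching: tuple[tuple[int, int], ...]) -> float:
    """Sum over pairs of |180° − ligand–Mn–ligand angle|."""
    return sum(abs(180.0 - ligand_angle(site, i, j)) for i, j in matching)


def pair_opposite_ligands(site: MnSite) -> tuple[tuple[int, int], ...]:
    """Resolve the three antipodal ligand pairs of a 6-coordinate site.

    Exhaustive search over the 15 perfect matchings for the one minimizing
    the total angular deviation from linearity.  The objective uses angles
    only, so bond-length distortion cannot change the pair identity.
    """
    if site.n_ligands != 6:
        raise GeometryError(f"site has {site.n_ligands} ligands; exactly 6 required")
    costs = [pairing_cost(site, m) for m in _MATCHINGS]
    return _MATCHINGS[int(np.argmin(costs))]


def compute_features(site: MnSite, axial_rule: str = "longest_pair") -> OctahedralFeatures:
    """Compute (E, A) for a 6-coordinate Mn site.

    With ``axial_rule="longest_pair"`` the axial pair is the antipodal pair
    with the greatest mean Mn–ligand distance (Jahn–Teller elongation is
    axial); E averages the remaining four distances.  Near-exact ties
    (< 1e-9 Å) are broken deterministically by ligand index order and
    logged.  ``axial_rule="named_axis:i,j"`` forces ligands i and j axial.
    """
    if site.n_ligands != 6:
        raise GeometryError(f"site has {site.n_ligands} ligands; exactly 6 required")

    pairing = pair_opposite_ligands(site)
    dists = site.distances

    if axial_rule == "longest_pair":
        means = [float(np.mean([dists[i], dists[j]])) for i, j in pairing]
        best = max(means)
        tied = [k for k, m in enumerate(means) if abs(m - best) < 1e-9]
        if len(tied) > 1:
            logger.info("axial pair tie (<1e-9 Å) at site %s; breaking by ligand index order",
                        site.site_label or site.serial)
        axial_idx = min(tied, key=lambda k: pairing[k])
    elif axial_rule.startswith("named_axis"):
        try:
            i, j = (int(x) for x in axial_rule.split(":", 1)[1].split(","))
        except (IndexError, ValueError) as exc:
            raise GeometryError(f"bad axial_rule {axial_rule!r}; expected 'named_axis:i,j'") from exc
        want = tuple(sorted((i, j)))
        if want not in pairing:
            raise GeometryError(f"ligands {want} are not an antipodal pair of this site")
        axial_idx = pairing.index(want)
    else:
        raise GeometryError(f"unknown axial_rule {axial_rule!r}")

    ax = set(pairing[axial_idx])
    eq = [i for i in range(6) if i not in ax]
    return OctahedralFeatures(
        E=float(np.mean(dists[eq])),
        A=float(np.mean(dists[sorted(ax)])),
        pairing=pairing,
        axial_pair_index=axial_idx,
    )
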