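"""Bond-valence sums: v = Σ_i exp((R0 − R_i)/B).

An independent, geometry-only cross-check on the classifier: each
metal–ligand bond contributes a valence that decays exponentially with
bond length, and the sum over the coordination shell estimates the metal
oxidation state.  R0 is tabulated per (oxidation state, ligand element);
B defaults to the universal 0.37 Å constant.  ``calibrate_r0`` refits R0
against reference sites of known oxidation state.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import brentq

from .structure_io import MnSite

DEFAULT_B = 0.37
R0_BOUNDS = (1.5, 2.2)

_STATE_NAMES = {2: "II", 3: "III", 4: "IV"}
_NAME_STATES = {v: k for k, v in _STATE_NAMES.items()}


class BVSError(ValueError):
    pass


def _as_state(state: int | str) -> int:
    if isinstance(state, str):
        state = state.strip()
        if state.upper() in _NAME_STATES:
            return _NAME_STATES[state.upper()]
        try:
            return int(state)
        except ValueError:
            raise BVSError(f"unknown oxidation state {state!r}") from None
    return int(state)


@dataclass
class BVSParams:
    """R0 (Å) keyed by (oxidation state, ligand element), plus B (Å)."""

    r0: dict[tuple[int, str], float] = field(default_factory=dict)
    b: dict[tuple[int, str], float] = field(default_factory=dict)
    default_b: float = DEFAULT_B

    def get_r0(self, state: int | str, element: str) -> float:
        key = (_as_state(state), element.upper())
        try:
            return self.r0[key]
        except KeyError:
            raise BVSError(
                f"no R0 parameter for state Mn({_STATE_NAMES.get(key[0], key[0])})"
                f" with ligand element {key[1]}") from None

    def get_b(self, state: int | str, element: str) -> float:
        return self.b.get((_as_state(state), element.upper()), self.default_b)

    def set_r0(self, state: int | str, element: str, value: float) -> None:
        self.r0[(_as_state(state), element.upper())] = float(value)

    def copy(self) -> "BVSParams":
        return BVSParams(dict(self.r0), dict(self.b), self.default_b)

    @classmethod
    def from_file(cls, path: str | Path) -> "BVSParams":
        """Load a plain-text parameter table (state, element, R0, B[, source])."""
        params = cls()
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].lstrip().startswith("#"):
                    continue
                state, element, r0, b = row[0], row[1], float(row[2]), float(row[3])
                key = (_as_state(state.strip()), element.strip().upper())
                params.r0[key] = r0
                params.b[key] = b
        if not params.r0:
            raise BVSError(f"no parameter rows found in {path}")
        return params


def default_params() -> BVSParams:
    """The packaged Mn(II/III/IV)–O/N reference parameters."""
    with resources.as_file(resources.files("mnox.data") / "bvs_params.tsv") as p:
        return BVSParams.from_file(p)


@dataclass
class BVSResult:
    """Valence sum for one assumed state, or a full candidate assignment."""

    v: float
    contributions: list[float]
    assumed_state: int
    assigned_state: int | None = None
    candidate_table: list[tuple[int, float, float]] | None = None  # (state, v, |v-state|)

    @property
    def assigned_label(self) -> str | None:
        return None if self.assigned_state is None else _STATE_NAMES[self.assigned_state]


def bond_valence_sum(
    distances: Sequence[tuple[float, str]],
    params: BVSParams,
    assumed_state: int | str,
) -> BVSResult:
    """Sum exp((R0 − R_i)/B) over (distance, element) bonds."""
    if not distances:
        raise BVSError("no bonds given")
    state = _as_state(assumed_state)
    contributions = [
        math.exp((params.get_r0(state, elem) - float(r)) / params.get_b(state, elem))
        for r, elem in distances
    ]
    return BVSResult(v=float(sum(contributions)), contributions=contributions,
                     assumed_state=state)


def site_bonds(site: MnSite) -> list[tuple[float, str]]:
    return [(lig.distance, lig.element) for lig in site.ligands]


def assign_bvs_oxidation(
    site: MnSite | Sequence[tuple[float, str]],
    params: BVSParams,
    candidates: Iterable[int | str] = (2, 3, 4),
) -> BVSResult:
    """Self-consistent assignment: evaluate v under each candidate state's
    R0 set and pick the candidate minimizing |v − candidate|; exact ties go
    to the lower state."""
    bonds = site_bonds(site) if isinstance(site, MnSite) else list(site)
    table: list[tuple[int, float, float]] = []
    for cand in candidates:
        state = _as_state(cand)
        res = bond_valence_sum(bonds, params, state)
        table.append((state, res.v, abs(res.v - state)))
    table.sort(key=lambda t: t[0])
    best = min(table, key=lambda t: (t[2], t[0]))
    chosen = bond_valence_sum(bonds, params, best[0])
    chosen.assigned_state = best[0]
    chosen.candidate_table = table
    return chosen


def calibrate_r0(
    reference_sites: Sequence[tuple[MnSite, int | str]],
    params: BVSParams,
    pairs: Iterable[tuple[int | str, str]] | None = None,
    bounds: tuple[float, float] = R0_BOUNDS,
) -> BVSParams:
    """Refit R0 per (state, element) so the mean valence-sum residual over
    the reference sites of that state vanishes.

    For each calibrated pair, R0 solves mean_sites(v(R0) − known_state) = 0
    by 1-D root bracketing inside ``bounds``; other parameters are held at
    their current values.  B is kept fixed.
    """
    refs = [(site, _as_state(state)) for site, state in reference_sites]
    if pairs is None:
        seen = {(state, lig.element) for site, state in refs for lig in site.ligands}
        pairs = sorted(seen)
    else:
        pairs = [(_as_state(s), e.upper()) for s, e in pairs]

    out = params.copy()
    for state, element in pairs:
        sites = [(site, s) for site, s in refs if s == state
                 and any(l.element == element for l in site.ligands)]
        if not sites:
            raise BVSError(f"no reference site for state {state} with {element} ligands")
        b_val = out.get_b(state, element)

        def residual(r0: float) -> float:
            trial = out.copy()
            trial.set_r0(state, element, r0)
            vs = [bond_valence_sum(site_bonds(site), trial, state).v for site, _ in sites]
            return float(np.mean(vs)) - state

        lo, hi = bounds
        f_lo, f_hi = residual(lo), residual(hi)
        if f_lo * f_hi > 0:
            raise BVSError(
                f"cannot bracket R0 for (state {state}, {element}) in {bounds}: "
                f"residuals ({f_lo:.3g}, {f_hi:.3g})")
        r0 = brentq(residual, lo, hi, xtol=1e-12, rtol=8.9e-16)
        if abs(residual(r0)) > 1e-8:
            raise BVSError(f"calibration residual too large for (state {state}, {element})")
        out.set_r0(state, element, r0)
    return out
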