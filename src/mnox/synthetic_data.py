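"""Synthetic inputs with known ground truth.

Two families of generators:

* feature tables — a 3-component 2-D Gaussian mixture in (E, A) space at
  the reference cluster centers with a configurable mislabeling rate,
  emulating a curated small-molecule database;
* coordinate files — minimal PDB files of single octahedral Mn sites or
  whole 4-Mn clusters, written together with exact ground truth (true
  pairing, axial axis, per-bond distances, labels and S state).

Everything is bit-reproducible given a seed.  Coordinates are quantized to
the precision actually written to the PDB text *before* ground truth is
computed, so file round-trips are exact.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .oec_pipeline import SStateAssignment, assign_s_state
from .structure_io import Atom
from .training import LABELS, LabeledFeatureTable

#: Reference cluster centers (E, A) in Å for the three oxidation classes.
REFERENCE_CENTERS: dict[str, tuple[float, float]] = {
    "II": (2.18, 2.28),
    "III": (1.95, 2.26),
    "IV": (1.91, 2.05),
}

#: Reference class counts of the curated database being emulated.
REFERENCE_COUNTS: dict[str, int] = {"II": 1734, "III": 835, "IV": 107}

#: Default isotropic within-class standard deviation (Å).
DEFAULT_SIGMA = 0.03

#: Default fraction of rows whose recorded label disagrees with the class
#: that generated their features (the curated database's ~5% label noise).
DEFAULT_MISLABEL_RATE = 0.05


# ---------------------------------------------------------------------------
# feature-table mixture
# ---------------------------------------------------------------------------

def _default_covariances() -> dict[str, np.ndarray]:
    return {lab: np.eye(2) * DEFAULT_SIGMA**2 for lab in LABELS}


@dataclass
class MixtureSpec:
    """3-component Gaussian mixture over (E, A) with label noise."""

    centers: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(REFERENCE_CENTERS))
    covariances: dict[str, np.ndarray] = field(default_factory=_default_covariances)
    counts: dict[str, int] = field(default_factory=lambda: dict(REFERENCE_COUNTS))
    mislabel_rate: float = DEFAULT_MISLABEL_RATE
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.mislabel_rate <= 1.0:
            raise ValueError("mislabel_rate must be in [0, 1]")
        for lab in LABELS:
            if self.counts.get(lab, 0) < 0:
                raise ValueError("counts must be non-negative")
            cov = np.asarray(self.covariances[lab], dtype=float)
            if cov.shape != (2, 2) or np.any(np.linalg.eigvalsh(cov) < -1e-12):
                raise ValueError(f"covariance for {lab} not a 2x2 PSD matrix")

    def with_sigma(self, sigma: float) -> "MixtureSpec":
        return replace(self, covariances={lab: np.eye(2) * sigma**2 for lab in LABELS})


@dataclass
class SyntheticTable:
    """A generated feature table plus its hidden ground-truth labels."""

    table: LabeledFeatureTable
    true_labels: np.ndarray     # per-row class that generated the features

    def label_agreement(self, labels: Sequence[str]) -> float:
        """Fraction of rows where ``labels`` matches the ground truth."""
        labels = np.asarray(labels, dtype=object)
        return float(np.mean(labels == self.true_labels))


def gen_feature_table(spec: MixtureSpec) -> SyntheticTable:
    """Sample the labeled mixture.

    Per class, exactly ``counts[label]`` rows carry that recorded label.
    With probability ``mislabel_rate`` a row is mislabeled: its features
    are drawn from one of the *other* two class Gaussians (chosen
    uniformly), so the recorded label disagrees with the generating class.
    The generating class is returned separately as ground truth.
    """
    if sum(spec.counts.get(lab, 0) for lab in LABELS) < 3:
        raise ValueError("total count must be >= 3")
    rng = np.random.default_rng(spec.seed)

    ids: list[str] = []
    visible: list[str] = []
    truth: list[str] = []
    feats: list[np.ndarray] = []
    for lab in LABELS:
        n = spec.counts.get(lab, 0)
        others = [o for o in LABELS if o != lab]
        for k in range(n):
            true_lab = lab
            if rng.random() < spec.mislabel_rate:
                true_lab = others[int(rng.integers(len(others)))]
            x = rng.multivariate_normal(
                np.asarray(spec.centers[true_lab], float),
                np.asarray(spec.covariances[true_lab], float))
            ids.append(f"syn-{lab}-{k:05d}")
            visible.append(lab)
            truth.append(true_lab)
            feats.append(x)

    order = rng.permutation(len(ids))
    X = np.vstack(feats)[order]
    df = pd.DataFrame({
        "id": [ids[i] for i in order],
        "E": X[:, 0],
        "A": X[:, 1],
        "label": [visible[i] for i in order],
    })
    return SyntheticTable(
        table=LabeledFeatureTable(df),
        true_labels=np.array([truth[i] for i in order], dtype=object))


# ---------------------------------------------------------------------------
# coordinate-file generators
# ---------------------------------------------------------------------------

@dataclass
class OctahedronSpec:
    """Geometry recipe for one synthetic octahedral Mn site."""

    equatorial: float = 1.95
    axial: float = 2.26
    angular_jitter_deg: float = 0.0
    distance_jitter: float = 0.0
    elements: tuple[str, ...] = ("O",) * 6
    label: str = "III"

    def __post_init__(self) -> None:
        if self.equatorial <= 0 or self.axial <= 0:
            raise ValueError("bond lengths must be positive")
        if self.angular_jitter_deg < 0 or self.distance_jitter < 0:
            raise ValueError("jitters must be non-negative")
        if len(self.elements) != 6:
            raise ValueError("exactly 6 ligand elements required")

    @property
    def max_bond(self) -> float:
        return max(self.equatorial, self.axial) + 4.0 * self.distance_jitter


def octahedron_for_label(label: str, **kwargs) -> OctahedronSpec:
    """An octahedron whose (E, A) sit at a reference cluster center."""
    e, a = REFERENCE_CENTERS[label]
    return OctahedronSpec(equatorial=e, axial=a, label=label, **kwargs)


@dataclass
class OctahedronTruth:
    """Ground truth of one generated site, from the written coordinates."""

    label: str
    E: float
    A: float
    distances: np.ndarray                      # written-precision, ligand order
    pairing: tuple[tuple[int, int], ...]       # ((0,1), (2,3), (4,5))
    axial_pair: tuple[int, int]
    mn_coord: np.ndarray

    def to_dict(self) -> dict:
        return {
            "label": self.label, "E": self.E, "A": self.A,
            "distances": self.distances.tolist(),
            "pairing": [list(p) for p in self.pairing],
            "axial_pair": list(self.axial_pair),
            "mn_coord": self.mn_coord.tolist(),
        }


def _format_coord(v: float) -> str:
    """Widest representation that fits the 8-column PDB coordinate field."""
    for fmt in ("%8.5f", "%8.4f", "%8.3f"):
        s = fmt % v
        if len(s) == 8:
            return s
    raise ValueError(f"coordinate {v} out of PDB range")


def _quantize(coord: np.ndarray) -> np.ndarray:
    return np.array([float(_format_coord(v)) for v in coord])


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation via QR of a Gaussian matrix."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def _signed_permutation(rng: np.random.Generator) -> np.ndarray:
    """Random octahedral-symmetry rotation (keeps grid-exact coordinates)."""
    while True:
        perm = rng.permutation(3)
        signs = rng.integers(0, 2, size=3) * 2 - 1
        m = np.zeros((3, 3))
        for i, (p, s) in enumerate(zip(perm, signs)):
            m[i, p] = s
        if np.linalg.det(m) > 0:
            return m


def _jitter_direction(u: np.ndarray, sigma_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotate unit vector u by angle ~|N(0, sigma)| about a random normal axis."""
    if sigma_deg == 0:
        return u
    angle = np.radians(rng.normal(0.0, sigma_deg))
    helper = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(helper, u)) > 0.9:
        helper = np.array([0.0, 1.0, 0.0])
    axis1 = np.cross(u, helper)
    axis1 /= np.linalg.norm(axis1)
    axis2 = np.cross(u, axis1)
    phi = rng.uniform(0, 2 * np.pi)
    axis = np.cos(phi) * axis1 + np.sin(phi) * axis2
    # Rodrigues rotation of u about axis (axis ⊥ u)
    return np.cos(angle) * u + np.sin(angle) * np.cross(axis, u)


# ligand order: +x, -x, +y, -y (equatorial), +z, -z (axial)
_OCTA_DIRECTIONS = np.array([
    [1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1],
], dtype=float)
_TRUE_PAIRING = ((0, 1), (2, 3), (4, 5))
_AXIAL_PAIR = (4, 5)


def _build_octahedron(
    spec: OctahedronSpec,
    rng: np.random.Generator,
    mn_coord: np.ndarray,
    rotation: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (quantized mn coord, quantized 6x3 ligand coords)."""
    if rotation is None:
        if spec.angular_jitter_deg == 0:
            rotation = _signed_permutation(rng)
        else:
            rotation = _random_rotation(rng)
    lengths = np.array([spec.equatorial] * 4 + [spec.axial] * 2)
    if spec.distance_jitter > 0:
        lengths = lengths + rng.normal(0.0, spec.distance_jitter, size=6)
        lengths = np.clip(lengths, 0.5, None)
    mn = _quantize(np.asarray(mn_coord, float))
    ligs = np.vstack([
        _quantize(mn + length * (rotation @ _jitter_direction(d, spec.angular_jitter_deg, rng)))
        for d, length in zip(_OCTA_DIRECTIONS, lengths)
    ])
    return mn, ligs


def _truth_from_coords(spec: OctahedronSpec, mn: np.ndarray, ligs: np.ndarray) -> OctahedronTruth:
    dists = np.linalg.norm(ligs - mn, axis=1)
    return OctahedronTruth(
        label=spec.label,
        E=float(np.mean(dists[:4])),
        A=float(np.mean(dists[4:])),
        distances=dists,
        pairing=_TRUE_PAIRING,
        axial_pair=_AXIAL_PAIR,
        mn_coord=mn,
    )


def write_pdb(atoms: Sequence[Atom], path: str | Path) -> None:
    """Write atoms as fixed-column HETATM records (one model)."""
    lines = []
    for a in atoms:
        name = a.name if len(a.element) == 2 else f" {a.name}"
        x, y, z = (_format_coord(v) for v in a.coord)
        lines.append(
            f"HETATM{a.serial:>5d} {name:<4.4s} {a.res_name:<3.3s} {a.chain_id:1.1s}"
            f"{a.res_seq:>4d}    {x}{y}{z}{a.occupancy:6.2f}{0.0:6.2f}"
            f"          {a.element:>2.2s}")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def gen_octahedron_file(
    spec: OctahedronSpec,
    path: str | Path,
    seed: int = 0,
    mn_coord: Sequence[float] = (0.0, 0.0, 0.0),
) -> OctahedronTruth:
    """Write one Mn + 6 ligands under a random (seeded) orientation.

    With zero angular jitter the orientation is drawn from the exact
    octahedral rotations so that written coordinates stay grid-exact and
    (E, A) reproduce the spec'd lengths to full written precision.
    """
    rng = np.random.default_rng(seed)
    mn, ligs = _build_octahedron(spec, rng, np.asarray(mn_coord, float))
    atoms = [Atom(serial=1, name="MN", element="MN", res_name="MNO", res_seq=1,
                  chain_id="A", coord=mn)]
    counts: dict[str, int] = {}
    for i, (coord, elem) in enumerate(zip(ligs, spec.elements)):
        counts[elem] = counts.get(elem, 0) + 1
        atoms.append(Atom(serial=i + 2, name=f"{elem.upper()}{counts[elem]}",
                          element=elem.upper(), res_name="MNO", res_seq=1,
                          chain_id="A", coord=coord))
    write_pdb(atoms, path)
    return _truth_from_coords(spec, mn, ligs)


# ---------------------------------------------------------------------------
# OEC cluster generator
# ---------------------------------------------------------------------------

@dataclass
class MonomerTruth:
    labels: tuple[str, str, str, str]
    assignment: SStateAssignment
    sites: list[OctahedronTruth]

    def to_dict(self) -> dict:
        return {
            "labels": list(self.labels),
            "total_charge": self.assignment.total_charge,
            "s_index": self.assignment.s_index,
            "sites": [s.to_dict() for s in self.sites],
        }


@dataclass
class OECTruth:
    monomers: list[MonomerTruth]

    def to_dict(self) -> dict:
        return {"monomers": [m.to_dict() for m in self.monomers]}


def _mn_positions(core: float, dangler: float) -> np.ndarray:
    """Mn1–Mn3 cuboidal-core triangle plus the dangling Mn4."""
    mn1 = np.array([0.0, 0.0, 0.0])
    mn2 = np.array([core, 0.0, 0.0])
    mn3 = np.array([core / 2.0, core * np.sqrt(3) / 2.0, 0.0])
    mn4 = mn3 + np.array([0.0, dangler, 0.0])
    return np.vstack([mn1, mn2, mn3, mn4])


def gen_oec_file(
    monomer_specs: Sequence[Sequence[OctahedronSpec]],
    path: str | Path,
    seed: int = 0,
    named: bool = True,
    core_separation: float = 3.25,
    dangler_separation: float = 4.2,
    monomer_offset: float = 30.0,
    min_separation: float = 0.5,
    max_retries: int = 500,
) -> OECTruth:
    """Write one or more 4-Mn clusters with per-site octahedral shells.

    Each monomer takes 4 specs in canonical order (Mn1, Mn2, Mn3, Mn4 =
    dangler).  Octahedron orientations are resampled (bounded retries)
    until no foreign atom intrudes into another Mn's coordination shell
    and no two atoms come closer than ``min_separation``.  With
    ``named=False`` all Mn atoms are written as plain "MN", exercising the
    dangler ordering heuristic downstream.
    """
    rng = np.random.default_rng(seed)
    if any(len(specs) != 4 for specs in monomer_specs):
        raise ValueError("each monomer needs exactly 4 octahedron specs")

    chains = "ABCDEFGH"
    atoms: list[Atom] = []
    truths: list[MonomerTruth] = []
    serial = itertools.count(1)

    for m, specs in enumerate(monomer_specs):
        chain = chains[m % len(chains)]
        offset = np.array([monomer_offset * m, 0.0, 0.0])
        # large shells (e.g. all-Mn(II)) need a slightly expanded core for a
        # clash-free orientation to exist at all
        core = max(core_separation, 1.52 * max(s.max_bond for s in specs[:3]))
        mn_pos = _mn_positions(core, dangler_separation) + offset
        # per-Mn shell-exclusion radius: a foreign atom closer to Mn j than
        # j's own longest bond could displace one of its six nearest ligands
        guards = [s.max_bond + 0.05 for s in specs]

        site_truths: list[OctahedronTruth] = []
        site_ligands: list[np.ndarray] = []
        placed: list[np.ndarray] = []
        for k, spec in enumerate(specs):
            ok = False
            for _ in range(max_retries):
                mn, ligs = _build_octahedron(
                    spec, rng, mn_pos[k], rotation=_random_rotation(rng))
                clash = False
                for j in range(4):
                    if j == k:
                        continue
                    if np.any(np.linalg.norm(ligs - mn_pos[j], axis=1) < guards[j]):
                        clash = True
                        break
                if not clash and placed:
                    prev = np.vstack(placed)
                    d = np.linalg.norm(ligs[:, None, :] - prev[None, :, :], axis=2)
                    clash = bool(np.min(d) < min_separation)
                if not clash:
                    ok = True
                    break
            if not ok:
                raise RuntimeError(
                    f"could not place octahedron Mn{k + 1} of monomer {m + 1} "
                    f"after {max_retries} retries")
            placed.extend(ligs)
            site_truths.append(_truth_from_coords(spec, mn, ligs))
            site_ligands.append(ligs)

        for k, st in enumerate(site_truths):
            # unnamed Mn atoms need distinct residues: a PDB residue cannot
            # hold two atoms with the same name
            mn_name = f"MN{k + 1}" if named else "MN"
            atoms.append(Atom(serial=next(serial), name=mn_name, element="MN",
                              res_name="OEX", res_seq=1 if named else k + 1,
                              chain_id=chain, coord=st.mn_coord))
        elem_counts: dict[str, int] = {}
        for spec, ligs in zip(specs, site_ligands):
            for coord, elem in zip(ligs, spec.elements):
                elem = elem.upper()
                elem_counts[elem] = elem_counts.get(elem, 0) + 1
                atoms.append(Atom(serial=next(serial),
                                  name=f"{elem}{elem_counts[elem]}", element=elem,
                                  res_name="OEX", res_seq=9, chain_id=chain,
                                  coord=coord))
        truths.append(MonomerTruth(
            labels=tuple(s.label for s in specs),  # type: ignore[arg-type]
            assignment=assign_s_state([s.label for s in specs], monomer_id=chain),
            sites=site_truths,
        ))

    write_pdb(atoms, path)
    return OECTruth(monomers=truths)
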