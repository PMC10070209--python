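"""End-to-end S-state prediction for Mn4 clusters (PSII OEC-style).

Locates the four-Mn cluster in each monomer of a structure, predicts a
per-ion oxidation label from the (E, A) features, sums the numeric charges
and maps the total to an S index (total charge 13, 14, 15, 16 for S0–S3,
extended linearly to negative indices for over-reduced structures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .geometry_features import compute_features
from .structure_io import MnSite, Structure, scan_mn_sites
from .training import LABEL_TO_CHARGE, LABELS, OxidationModel

logger = logging.getLogger(__name__)

#: Mn–Mn single-linkage threshold (Å) for grouping a cluster's ions.
MN_CLUSTER_LINKAGE = 6.0

#: Total charge of the S0 state; S index = total charge − 13.
S0_TOTAL_CHARGE = 13

_CANONICAL_NAMES = ("MN1", "MN2", "MN3", "MN4")


class OECError(ValueError):
    pass


@dataclass
class OECMnEntry:
    """One of the four Mn positions of a monomer's cluster."""

    position: int                     # 1..4
    serial: int
    site: MnSite | None               # None when < 6 allowed ligands were found
    n_neighbors: int


@dataclass
class OECMonomer:
    monomer_id: str
    entries: list[OECMnEntry]

    @property
    def sites(self) -> list[MnSite | None]:
        return [e.site for e in self.entries]


@dataclass
class SStateAssignment:
    """Per-monomer oxidation labels, their total charge and the S index."""

    monomer_id: str
    oxidations: tuple[str, str, str, str]
    total_charge: int
    s_index: int

    @property
    def oxidation_string(self) -> str:
        return ",".join(self.oxidations)


@dataclass
class MonomerPrediction:
    """Prediction outcome for one monomer; partial when a site failed."""

    monomer_id: str
    labels: list[str | None]
    failures: list[str] = field(default_factory=list)
    assignment: SStateAssignment | None = None

    @property
    def complete(self) -> bool:
        return self.assignment is not None


def assign_s_state(oxidations: Sequence[str], monomer_id: str = "") -> SStateAssignment:
    """Map 4 oxidation labels to a total charge and S index."""
    if len(oxidations) != 4:
        raise OECError(f"expected exactly 4 oxidation labels, got {len(oxidations)}")
    labels = tuple(str(o).upper() for o in oxidations)
    for lab in labels:
        if lab not in LABELS:
            raise OECError(f"unknown oxidation label {lab!r}")
    total = sum(LABEL_TO_CHARGE[lab] for lab in labels)
    return SStateAssignment(
        monomer_id=monomer_id, oxidations=labels, total_charge=total,
        s_index=total - S0_TOTAL_CHARGE)


def _connected_components(coords: np.ndarray, threshold: float) -> list[list[int]]:
    n = len(coords)
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    adj = d <= threshold
    seen = np.zeros(n, dtype=bool)
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.nonzero(adj[i] & ~seen)[0]:
                seen[j] = True
                stack.append(int(j))
        comps.append(sorted(comp))
    return comps


def extract_oec(
    structure: Structure,
    cutoff: float = 2.9,
    allowed_elements: Iterable[str] = ("O", "N"),
    linkage: float = MN_CLUSTER_LINKAGE,
) -> list[OECMonomer]:
    """Group Mn ions into per-monomer clusters of four and order them Mn1–Mn4.

    Grouping is by single-linkage proximity (chain ids differ between
    entries, so distance is the primary signal).  Ordering follows the
    canonical atom names MN1–MN4 when all four are present; otherwise Mn4
    is the dangler (greatest mean distance to the other three) and Mn1–Mn3
    follow atom serial order.  Components with fewer than four Mn are
    skipped with a warning.
    """
    mn_atoms = structure.select(element="MN")
    if not mn_atoms:
        raise OECError(f"no Mn atoms in {structure.source or 'structure'}")
    model_ids = sorted({a.model_id for a in mn_atoms})
    if len(model_ids) > 1:
        logger.warning("multiple models present; using model %s", model_ids[0])
    mn_atoms = [a for a in mn_atoms if a.model_id == model_ids[0]]

    scan = scan_mn_sites(structure, cutoff=cutoff, allowed_elements=allowed_elements,
                         required_coordination=6)
    site_by_serial = {s.serial: s for s in scan.sites}
    neighbors_by_serial = {s.serial: 6 for s in scan.sites}
    neighbors_by_serial.update({r.serial: r.n_neighbors for r in scan.rejected})

    coords = np.array([a.coord for a in mn_atoms])
    monomers: list[OECMonomer] = []
    for comp in _connected_components(coords, linkage):
        atoms = [mn_atoms[i] for i in comp]
        if len(atoms) < 4:
            logger.warning("Mn cluster with %d ions (serials %s) skipped; 4 required",
                           len(atoms), [a.serial for a in atoms])
            continue
        if len(atoms) > 4:
            named = [a for a in atoms if a.name.upper() in _CANONICAL_NAMES]
            if len(named) == 4:
                atoms = named
            else:
                logger.warning("Mn cluster with %d ions skipped; cannot resolve 4", len(atoms))
                continue

        names = [a.name.upper() for a in atoms]
        if sorted(names) == sorted(_CANONICAL_NAMES):
            ordered = sorted(atoms, key=lambda a: a.name.upper())
        else:
            pos = np.array([a.coord for a in atoms])
            mean_d = [
                float(np.mean([np.linalg.norm(pos[i] - pos[j]) for j in range(4) if j != i]))
                for i in range(4)
            ]
            dangler = int(np.argmax(mean_d))
            core = sorted((a for i, a in enumerate(atoms) if i != dangler),
                          key=lambda a: a.serial)
            ordered = core + [atoms[dangler]]

        chains = {a.chain_id for a in ordered}
        monomer_id = ordered[0].chain_id if len(chains) == 1 else "+".join(sorted(chains))
        monomer_id = f"{monomer_id}:{len(monomers) + 1}"
        entries = [
            OECMnEntry(
                position=k + 1,
                serial=a.serial,
                site=site_by_serial.get(a.serial),
                n_neighbors=neighbors_by_serial.get(a.serial, 0),
            )
            for k, a in enumerate(ordered)
        ]
        for entry, atom in zip(entries, ordered):
            if entry.site is not None:
                entry.site.site_label = f"Mn{entry.position}"
                entry.site.monomer_id = monomer_id
        monomers.append(OECMonomer(monomer_id=monomer_id, entries=entries))
    if not monomers:
        raise OECError("no 4-Mn cluster found")
    return monomers


def predict_oec(
    structure: Structure,
    model: OxidationModel,
    cutoff: float = 2.9,
    allowed_elements: Iterable[str] = ("O", "N"),
    axial_rule: str = "longest_pair",
) -> list[MonomerPrediction]:
    """Predict per-ion oxidation labels and the S state for every monomer.

    Monomers are processed independently.  A Mn position without six
    allowed ligands is recorded as a per-site failure and the monomer is
    marked partially predicted (no S index fabricated).
    """
    predictions: list[MonomerPrediction] = []
    for monomer in extract_oec(structure, cutoff=cutoff, allowed_elements=allowed_elements):
        labels: list[str | None] = []
        failures: list[str] = []
        for entry in monomer.entries:
            if entry.site is None:
                labels.append(None)
                failures.append(
                    f"Mn{entry.position} (serial {entry.serial}): "
                    f"{entry.n_neighbors} allowed ligands within {cutoff} Å; 6 required")
                continue
            feats = compute_features(entry.site, axial_rule=axial_rule)
            labels.append(model.predict_one(feats))
        pred = MonomerPrediction(monomer_id=monomer.monomer_id, labels=labels,
                                 failures=failures)
        if all(lab is not None for lab in labels):
            pred.assignment = assign_s_state(labels, monomer_id=monomer.monomer_id)  # type: ignore[arg-type]
        else:
            logger.warning("monomer %s partially predicted: %s",
                           monomer.monomer_id, "; ".join(failures))
        predictions.append(pred)
    return predictions


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

@dataclass
class PredictionReport:
    """Tabular reported-vs-predicted comparison plus summary histograms."""

    rows: pd.DataFrame
    s_state_histogram: dict[int, dict[int, int]]      # monomer -> {s_index: count}
    oxidation_distribution: dict[int, dict[str, int]]  # Mn position -> {label: count}
    match_counts: dict[int, int]                       # monomer -> matched rows

    def __len__(self) -> int:
        return len(self.rows)


def build_report(
    rows: pd.DataFrame,
    reported: Mapping[tuple[str, int], int] | None = None,
) -> PredictionReport:
    """Assemble the comparison report from long-format prediction rows.

    ``rows`` needs columns ``pdb_id``, ``monomer`` (1-based int) and
    ``predicted_s``; optional ``reported_s`` and ``oxidations`` (a string
    like ``"III,IV,IV,III"``).  ``reported`` may override/supply reported
    states keyed by (pdb_id, monomer); rows without a reported state get a
    blank comparison.
    """
    required = {"pdb_id", "monomer", "predicted_s"}
    missing = required - set(rows.columns)
    if missing:
        raise OECError(f"report rows missing columns {sorted(missing)}")
    df = rows.copy().reset_index(drop=True)
    if "reported_s" not in df.columns:
        df["reported_s"] = pd.NA
    if reported is not None:
        df["reported_s"] = [
            reported.get((r.pdb_id, int(r.monomer)), r.reported_s)
            for r in df.itertuples()
        ]

    def flag(row) -> object:
        if pd.isna(row["reported_s"]) or pd.isna(row["predicted_s"]):
            return pd.NA
        return int(row["reported_s"]) == int(row["predicted_s"])

    df["match"] = df.apply(flag, axis=1)

    s_hist: dict[int, dict[int, int]] = {}
    match_counts: dict[int, int] = {}
    for monomer, grp in df.groupby("monomer"):
        pred = grp["predicted_s"].dropna().astype(int)
        s_hist[int(monomer)] = dict(pred.value_counts().sort_index().items())
        match_counts[int(monomer)] = int((grp["match"] == True).sum())  # noqa: E712

    ox_dist: dict[int, dict[str, int]] = {}
    if "oxidations" in df.columns:
        for pos in range(4):
            counts: dict[str, int] = {lab: 0 for lab in LABELS}
            for val in df["oxidations"].dropna():
                parts = [p.strip().upper() for p in str(val).split(",")]
                if len(parts) == 4 and parts[pos] in counts:
                    counts[parts[pos]] += 1
            ox_dist[pos + 1] = counts

    return PredictionReport(rows=df, s_state_histogram=s_hist,
                            oxidation_distribution=ox_dist, match_counts=match_counts)


def predictions_to_rows(
    pdb_id: str, predictions: Sequence[MonomerPrediction],
) -> pd.DataFrame:
    """Convert per-structure predictions to long-format report rows."""
    records = []
    for i, pred in enumerate(predictions, start=1):
        records.append({
            "pdb_id": pdb_id,
            "monomer": i,
            "monomer_id": pred.monomer_id,
            "predicted_s": pred.assignment.s_index if pred.complete else pd.NA,
            "oxidations": pred.assignment.oxidation_string if pred.complete else pd.NA,
            "total_charge": pred.assignment.total_charge if pred.complete else pd.NA,
            "failures": "; ".join(pred.failures) if pred.failures else "",
        })
    return pd.DataFrame.from_records(records)
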