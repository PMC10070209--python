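"""Loaders for the small reference tables shipped with the package."""

from __future__ import annotations

from importlib import resources

import pandas as pd


def load_psii_survey() -> pd.DataFrame:
    """Reported vs. model-predicted S-states for 38 published PSII structures.

    Columns: ``pdb_id``, ``method`` (XFEL/X-ray/cryoEM), ``reported_s``
    (experimental flash-protocol assignment), and per monomer ``m{1,2}_s``
    (predicted S index) and ``m{1,2}_ox`` (predicted per-ion oxidation
    labels, Mn1..Mn4).  Used as a bookkeeping fixture for the report
    builder and as a regression reference.
    """
    with resources.as_file(resources.files("mnox.data") / "psii_sstate_survey.csv") as p:
        return pd.read_csv(p)


def psii_survey_rows(survey: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format report rows (one per structure × monomer) from the survey."""
    if survey is None:
        survey = load_psii_survey()
    records = []
    for row in survey.itertuples():
        for monomer in (1, 2):
            records.append({
                "pdb_id": row.pdb_id,
                "monomer": monomer,
                "method": row.method,
                "reported_s": int(row.reported_s),
                "predicted_s": int(getattr(row, f"m{monomer}_s")),
                "oxidations": getattr(row, f"m{monomer}_ox"),
            })
    return pd.DataFrame.from_records(records)
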