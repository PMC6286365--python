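"""CSV readers/writers for every table the pipeline consumes or emits.

Documented schemas (all concentrations in µM; nM/pM only in rendering):

* plate:    ``plate_id, row, col, role, compound_id, conc_um, rfu``
* kinetic:  ``substrate_um, inhibitor_um, replicate, rate``
* PK:       ``matrix, time_h, conc, animal_id``
* EV:       ``condition, replicate, value``
* qPCR:     ``sample_id, group, gene, ct_target, ct_reference``
* results:  one row per compound with all dose-response fields
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .dose_response import DoseResponseResult
from .exceptions import SchemaError
from .pk import ConcentrationTimeProfile
from .plates import ROLES, PlateLayout, row_index
from .synth import PLATE_COLUMNS

__all__ = [
    "read_plate_csv",
    "write_plate_csv",
    "read_kinetic_csv",
    "read_pk_csv",
    "write_pk_csv",
    "read_grouped_csv",
    "read_qpcr_csv",
    "results_frame",
    "write_results_csv",
    "read_results_csv",
]

KINETIC_COLUMNS = ["substrate_um", "inhibitor_um", "replicate", "rate"]
PK_COLUMNS = ["matrix", "time_h", "conc", "animal_id"]
EV_COLUMNS = ["condition", "replicate", "value"]
QPCR_COLUMNS = ["sample_id", "group", "gene", "ct_target", "ct_reference"]
RESULT_COLUMNS = [
    "compound_id",
    "assay_id",
    "bottom",
    "top",
    "ic50_um",
    "hill",
    "r2",
    "n_asymptotes",
    "efficacy",
    "converged",
    "extrapolated",
    "crc_class",
    "doses_um",
    "response_pct",
]


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def read_plate_csv(path: str | Path, layout: PlateLayout | None = None) -> pd.DataFrame:
    """Read and validate a plate table.

    Checks the documented header, row labels (A–AF by default geometry),
    1-based column range, known roles, and rejects duplicate wells.
    """
    layout = layout or PlateLayout()
    df = pd.read_csv(path, keep_default_na=False, dtype={"compound_id": str, "row": str})
    _require_columns(df, PLATE_COLUMNS, "plate")
    df = df[PLATE_COLUMNS].copy()
    df["col"] = df["col"].astype(int)
    df["conc_um"] = df["conc_um"].astype(float)
    df["rfu"] = df["rfu"].astype(float)
    bad_roles = set(df["role"]) - set(ROLES)
    if bad_roles:
        raise SchemaError(f"unknown well role(s): {sorted(bad_roles)}")
    for label in df["row"].unique():
        try:
            idx = row_index(label)
        except Exception as exc:
            raise SchemaError(f"malformed row label {label!r}") from exc
        if idx >= layout.n_rows:
            raise SchemaError(f"row label {label!r} outside plate with {layout.n_rows} rows")
    if ((df["col"] < 1) | (df["col"] > layout.n_cols)).any():
        raise SchemaError(f"column index outside 1..{layout.n_cols}")
    dup = df.duplicated(subset=["plate_id", "row", "col"])
    if dup.any():
        wells = df.loc[dup, ["plate_id", "row", "col"]].head(5).to_dict("records")
        raise SchemaError(f"duplicate wells: {wells}")
    return df


def write_plate_csv(plate: pd.DataFrame, path: str | Path) -> None:
    plate[PLATE_COLUMNS].to_csv(path, index=False)


def read_kinetic_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    # replicate column is optional on input
    _require_columns(df, [c for c in KINETIC_COLUMNS if c != "replicate"], "kinetic")
    if "replicate" not in df.columns:
        df["replicate"] = 0
    return df[KINETIC_COLUMNS]


def read_pk_csv(path: str | Path) -> dict[str, ConcentrationTimeProfile]:
    """Read a PK table into one profile per matrix (plasma/brain)."""
    df = pd.read_csv(path)
    _require_columns(df, PK_COLUMNS, "PK")
    profiles = {}
    for matrix, g in df.groupby("matrix"):
        times = np.sort(g["time_h"].unique())
        counts = g.groupby("time_h")["conc"].size()
        if counts.nunique() != 1:
            raise SchemaError(
                f"matrix {matrix!r}: unequal animals per time point; pad or subset first"
            )
        n = int(counts.iloc[0])
        conc = np.empty((times.size, n))
        ids = np.empty((times.size, n), dtype=object)
        for i, t in enumerate(times):
            sub = g[g["time_h"] == t]
            conc[i] = sub["conc"].to_numpy()
            ids[i] = sub["animal_id"].to_numpy()
        profiles[str(matrix)] = ConcentrationTimeProfile(
            matrix_label=str(matrix), times=times, concentrations=conc, animal_ids=ids
        )
    return profiles


def write_pk_csv(profiles: dict[str, ConcentrationTimeProfile], path: str | Path) -> None:
    pd.concat([p.to_frame() for p in profiles.values()]).to_csv(path, index=False)


def read_grouped_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, EV_COLUMNS, "grouped-count")
    return df[EV_COLUMNS]


def read_qpcr_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, QPCR_COLUMNS, "qPCR")
    return df[QPCR_COLUMNS]


def results_frame(results: dict[str, DoseResponseResult]) -> pd.DataFrame:
    rows = []
    for res in results.values():
        rows.append(
            {
                "compound_id": res.compound_id,
                "assay_id": res.assay_id,
                "bottom": res.bottom,
                "top": res.top,
                "ic50_um": res.ic50_um,
                "hill": res.hill,
                "r2": res.r2,
                "n_asymptotes": res.n_asymptotes,
                "efficacy": res.efficacy,
                "converged": res.converged,
                "extrapolated": res.extrapolated,
                "crc_class": res.crc_class,
                "doses_um": "|".join(f"{d:g}" for d in res.doses),
                "response_pct": "|".join(f"{r:.4f}" for r in res.response),
            }
        )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results_csv(results: dict[str, DoseResponseResult], path: str | Path) -> None:
    results_frame(results).to_csv(path, index=False)


def read_results_csv(path: str | Path) -> dict[str, DoseResponseResult]:
    df = pd.read_csv(path, keep_default_na=False, dtype={"compound_id": str})
    _require_columns(df, RESULT_COLUMNS, "results")
    out = {}
    for r in df.itertuples(index=False):
        out[r.compound_id] = DoseResponseResult(
            compound_id=r.compound_id,
            assay_id=r.assay_id,
            doses=tuple(float(x) for x in str(r.doses_um).split("|") if x),
            response=tuple(float(x) for x in str(r.response_pct).split("|") if x),
            bottom=float(r.bottom),
            top=float(r.top),
            ic50_um=float(r.ic50_um),
            hill=float(r.hill),
            r2=float(r.r2),
            n_asymptotes=int(r.n_asymptotes),
            efficacy=float(r.efficacy),
            converged=bool(r.converged),
            extrapolated=bool(r.extrapolated),
            crc_class=float(r.crc_class) if str(r.crc_class) != "" else None,
        )
    return out
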