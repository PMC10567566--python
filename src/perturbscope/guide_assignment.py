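"""Per-nucleus gRNA assignment from raw guide count tables.

Three simultaneous filters remove spurious guide records — low read
coverage (reads/UMI), a single captured molecule, or a small share of
the nucleus's guide UMIs — and the survivors are called unique,
multiplet or unassigned per nucleus.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GuideLibrary",
    "filter_guide_records",
    "assign_guides",
    "assignment_summary",
]

GUIDE_TABLE_COLUMNS = ["barcode", "guide_id", "umi_count", "read_count"]


@dataclass
class GuideLibrary:
    """Mapping guide_id -> (target gene, is_control)."""

    table: pd.DataFrame  # columns: guide_id, target, is_control

    def __post_init__(self) -> None:
        required = {"guide_id", "target", "is_control"}
        if not required <= set(self.table.columns):
            raise ValueError(f"guide library needs columns {sorted(required)}")
        if self.table["guide_id"].duplicated().any():
            raise ValueError("duplicate guide ids in library")
        self._targets = self.table.set_index("guide_id")["target"]
        self._is_control = self.table.set_index("guide_id")["is_control"]

    def target_of(self, guide_id: str) -> str:
        return self._targets[guide_id]

    def known(self, guide_ids) -> pd.Series:
        return pd.Index(guide_ids).isin(self._targets.index)

    @classmethod
    def from_tsv(cls, path) -> "GuideLibrary":
        return cls(pd.read_csv(path, sep="\t"))


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    missing = set(GUIDE_TABLE_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"guide table missing columns {sorted(missing)}")
    if len(records):
        if (records["umi_count"] < 1).any():
            raise ValueError("umi_count must be >= 1")
        if (records["read_count"] < records["umi_count"]).any():
            raise ValueError("read_count must be >= umi_count")
        if records.duplicated(["barcode", "guide_id"]).any():
            raise ValueError("(barcode, guide_id) must be unique")
    return records


def filter_guide_records(
    records: pd.DataFrame,
    min_coverage: float = 60.0,
    min_umi: int = 2,
    min_fraction: float = 0.10,
    fraction_on_filtered: bool = False,
) -> pd.DataFrame:
    """Apply the coverage / UMI / fraction filters to raw guide records.

    A record survives iff ``read_count/umi_count >= min_coverage``,
    ``umi_count >= min_umi`` and its UMIs make up at least
    ``min_fraction`` of all guide UMIs of that barcode. All boundaries
    are inclusive (records strictly below a threshold are removed). By
    default the fraction denominator is the pre-filter per-barcode total;
    ``fraction_on_filtered=True`` recomputes it after the coverage and
    UMI filters.
    """
    if min_coverage <= 0 or min_umi <= 0 or min_fraction <= 0:
        raise ValueError("thresholds must be positive")
    records = _validate_records(records)
    if not len(records):
        return records.copy()

    coverage_ok = (records["read_count"] / records["umi_count"]) >= min_coverage
    umi_ok = records["umi_count"] >= min_umi
    base = records if not fraction_on_filtered else records[coverage_ok & umi_ok]
    totals = base.groupby("barcode")["umi_count"].transform("sum") if (
        not fraction_on_filtered
    ) else base.groupby("barcode")["umi_count"].sum().reindex(
        records["barcode"]
    ).to_numpy()
    frac_ok = records["umi_count"] / totals >= min_fraction
    frac_ok = frac_ok.fillna(False) if hasattr(frac_ok, "fillna") else frac_ok
    return records[coverage_ok & umi_ok & frac_ok].reset_index(drop=True)


def assign_guides(
    filtered: pd.DataFrame,
    library: GuideLibrary,
    all_barcodes=None,
) -> pd.DataFrame:
    """Call each barcode unique / multiplet / unassigned from filtered records.

    ``all_barcodes`` (e.g. the expression-matrix barcodes) adds
    ``unassigned`` rows for barcodes with no surviving guide record.
    Guides absent from the library are collected (not silently dropped):
    the returned frame carries them in ``.attrs['unknown_guides']``.
    """
    filtered = _validate_records(filtered)
    unknown = sorted(
        set(filtered["guide_id"]) - set(library.table["guide_id"])
    ) if len(filtered) else []
    known = filtered[library.known(filtered["guide_id"])] if len(filtered) else filtered

    rows = []
    if len(known):
        for barcode, grp in known.groupby("barcode", sort=False):
            if len(grp) == 1:
                rec = grp.iloc[0]
                rows.append(
                    (
                        barcode,
                        "unique",
                        rec["guide_id"],
                        library.target_of(rec["guide_id"]),
                        int(rec["umi_count"]),
                    )
                )
            else:
                rows.append((barcode, "multiplet", None, None, None))
    result = pd.DataFrame(
        rows, columns=["barcode", "status", "guide_id", "target", "umi_count"],
        dtype=object,
    )
    if all_barcodes is not None:
        missing = pd.Index(all_barcodes).difference(result["barcode"])
        if len(missing):
            extra = pd.DataFrame(
                {
                    "barcode": missing,
                    "status": "unassigned",
                    "guide_id": None,
                    "target": None,
                    "umi_count": None,
                },
                dtype=object,
            )
            result = (
                pd.concat([result, extra], ignore_index=True)
                if len(result)
                else extra
            )
    result.attrs["unknown_guides"] = unknown
    return result


def assignment_summary(
    assignments: pd.DataFrame,
    by: str = "target",
    metadata: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Nucleus counts per stratum plus unique/multiplet/unassigned fractions.

    ``by`` is ``guide``, ``target`` or ``cell_type`` (the latter requires
    ``metadata`` indexed by barcode with a ``cell_type`` column).
    """
    df = assignments.copy()
    if by == "guide":
        key = "guide_id"
    elif by == "target":
        key = "target"
    elif by == "cell_type":
        if metadata is None:
            raise ValueError("cell_type summary requires metadata")
        df["cell_type"] = metadata["cell_type"].reindex(df["barcode"]).to_numpy()
        key = "cell_type"
    else:
        raise ValueError(f"unknown stratifier {by!r}")
    counts = (
        df[df["status"] == "unique"]
        .groupby(key, dropna=False)
        .size()
        .rename("n_unique")
        .to_frame()
    )
    n = len(df)
    status = df["status"].value_counts()
    counts.attrs["fractions"] = {
        s: float(status.get(s, 0)) / n if n else np.nan
        for s in ("unique", "multiplet", "unassigned")
    }
    return counts
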