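#!/usr/bin/env python
"""Export the deposited study workbook (XLSX) to seroclade's long TSV dialect.

The underlying per-individual measurements are deposited alongside the
publication as an XLSX workbook.  seroclade's core never parses binary
workbooks; this helper performs the documented one-off export:

    python scripts/export_s4_to_tsv.py S4_dataset.xlsx data/deposited/s4_cohort.tsv

The workbook is expected to hold one row per subject with columns for the
group code (Rh-DE, B-CD, B-DE, Ch-CG, Ch-SL, Ch-DE, H-DE — en/em dashes are
normalized to "-"), sex, age, and one column per biomarker; value cells may
be numeric or censor tokens like "< 1.71".  Adjust the column names below if
the deposited sheet differs — the point of this script is to make whatever
mapping is applied explicit and reviewable.

Requires openpyxl (install extra: `pip install seroclade[export]`).
"""

from __future__ import annotations

import argparse
import csv
import re
import sys
from pathlib import Path

GROUP_CODES = {"RH-DE": "Rh-DE", "B-CD": "B-CD", "B-DE": "B-DE", "CH-CG": "Ch-CG",
               "CH-SL": "Ch-SL", "CH-DE": "Ch-DE", "H-DE": "H-DE"}
META_HINTS = {
    "subject": "subject_id", "id": "subject_id", "individual": "subject_id",
    "group": "group", "species": "group", "population": "group",
    "sex": "sex", "gender": "sex",
    "age": "age_years", "weight": "weight_kg",
}
SEXES = {"m": "male", "male": "male", "f": "female", "female": "female"}


def normalize_group(raw: str) -> str | None:
    cleaned = re.sub(r"[‐-―−]", "-", str(raw)).strip().upper().replace(" ", "")
    return GROUP_CODES.get(cleaned)


def cell_text(value) -> str:
    if value is None:
        return ""
    return str(value).strip()


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("workbook", type=Path)
    parser.add_argument("out_tsv", type=Path)
    parser.add_argument("--sheet", default=None, help="Sheet name (default: first sheet).")
    args = parser.parse_args()

    try:
        import openpyxl
    except ImportError:
        sys.exit("openpyxl is required: pip install openpyxl")

    wb = openpyxl.load_workbook(args.workbook, data_only=True, read_only=True)
    ws = wb[args.sheet] if args.sheet else wb.worksheets[0]
    rows = ws.iter_rows(values_only=True)
    header = [cell_text(h) for h in next(rows)]

    meta_cols: dict[int, str] = {}
    marker_cols: dict[int, str] = {}
    for i, name in enumerate(header):
        low = name.lower()
        hit = next((v for k, v in META_HINTS.items() if low == k or low.startswith(k + " ")), None)
        if hit and hit not in meta_cols.values():
            meta_cols[i] = hit
        elif name:
            marker_cols[i] = name
    if "group" not in meta_cols.values() or "sex" not in meta_cols.values():
        sys.exit(f"could not locate group/sex columns in header: {header}")

    args.out_tsv.parent.mkdir(parents=True, exist_ok=True)
    written = skipped = 0
    with args.out_tsv.open("w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["subject_id", "group", "sex", "age_years", "weight_kg",
                         "biomarker", "units", "value"])
        for rowno, row in enumerate(rows, start=2):
            meta = {name: cell_text(row[i]) for i, name in meta_cols.items()}
            group = normalize_group(meta.get("group", ""))
            sex = SEXES.get(meta.get("sex", "").lower())
            if group is None or sex is None:
                skipped += 1
                continue
            sid = meta.get("subject_id") or f"{group}-{rowno:04d}"
            for i, marker in marker_cols.items():
                value = cell_text(row[i])
                if value in ("", "n. a.", "n.a.", "na", "NA"):
                    continue
                writer.writerow([sid, group, sex, meta.get("age_years", ""),
                                 meta.get("weight_kg", ""), marker, "", value])
                written += 1
    print(f"wrote {written} measurements to {args.out_tsv}; skipped {skipped} rows "
          "without a recognizable group/sex")


if __name__ == "__main__":
    main()
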