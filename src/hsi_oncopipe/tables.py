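"""Exact (decimal) aggregation checks over published per-patient tables.

The packaged CSVs under ``data/`` hold the study's printed per-patient
sample inventory, data-point counts and cross-validation metrics; the
check functions recompute totals and the cohort mean row from the
per-patient cells using exact decimal arithmetic, so 2-decimal rounding
is reproduced without float artifacts.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path

import pandas as pd

from hsi_oncopipe.errors import ContractError
from hsi_oncopipe.evaluation import METRIC_NAMES

_DATA = resources.files("hsi_oncopipe") / "data"


def _packaged(name: str):
    return _DATA / name


def load_sample_inventory(path=None) -> pd.DataFrame:
    """Per-sample inventory: patient, sample letter, tissue type, included flag."""
    return pd.read_csv(path or _packaged("table1_samples.csv"))


def load_datapoint_counts(path=None) -> pd.DataFrame:
    """Per-patient tumor / non-tumor data-point counts."""
    return pd.read_csv(path or _packaged("table2_counts.csv"))


def load_patient_metrics(path=None) -> pd.DataFrame:
    """Per-patient cross-validation metrics (strings; '-' marks undefined)."""
    return pd.read_csv(path or _packaged("table3_metrics.csv"), dtype=str)


def sample_counts(inventory: pd.DataFrame) -> dict[str, int]:
    """Counts of included samples, total and per tissue type."""
    inc = inventory[inventory["included"] == 1]
    out = {"total": int(len(inc))}
    for tissue, n in inc["tissue_type"].value_counts().items():
        out[tissue.lower()] = int(n)
    return out


def datapoint_totals(counts: pd.DataFrame) -> dict[str, int]:
    """Grand totals of data points across patients; checks row consistency."""
    if counts.empty:
        raise ContractError("empty count table")
    bad = counts[counts["total"] != counts["tumor"] + counts["non_tumor"]]
    if len(bad):
        raise ContractError(f"rows where tumor + non_tumor != total: {list(bad['patient'])}")
    return {
        "total": int(counts["total"].sum()),
        "tumor": int(counts["tumor"].sum()),
        "non_tumor": int(counts["non_tumor"].sum()),
    }


def round_half_up(value: Decimal, places: int = 2) -> Decimal:
    return value.quantize(Decimal(10) ** -places, rounding=ROUND_HALF_UP)


def mean_row_decimal(
    table: pd.DataFrame, return_counts: bool = False
) -> dict[str, Decimal | None] | tuple[dict[str, Decimal | None], dict[str, int]]:
    """Cohort mean row from per-patient cells, in exact decimal arithmetic.

    A cell counts toward its metric's mean when it parses as a number and
    the patient either has tumor tissue or the metric is specificity
    (tumor-free patients contribute only there).  Results are rounded to
    2 decimals, half up.
    """
    rows = table[table["patient"].str.lower() != "mean"]
    if rows.empty:
        raise ContractError("metrics table has no per-patient rows")
    out: dict[str, Decimal | None] = {}
    counts: dict[str, int] = {}
    for metric in METRIC_NAMES:
        vals = []
        for _, row in rows.iterrows():
            cell = str(row[metric]).strip()
            starred = str(row["tumor_free"]).strip() in {"1", "True", "true"}
            if starred and metric != "specificity":
                continue
            try:
                vals.append(Decimal(cell))
            except ArithmeticError:
                continue
        out[metric] = round_half_up(sum(vals) / len(vals)) if vals else None
        counts[metric] = len(vals)
    return (out, counts) if return_counts else out


def run_table_check(
    metrics_csv: str | Path | None = None,
    counts_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Recompute the mean row of a per-patient metrics table and compare it
    against the table's own printed Mean row, cell by cell at 2 decimals.

    Returns a frame with columns metric, printed, recomputed, match.
    """
    table = load_patient_metrics(metrics_csv)
    printed = table[table["patient"].str.lower() == "mean"]
    if printed.empty:
        raise ContractError("metrics table has no Mean row to check against")
    printed = printed.iloc[0]
    computed = mean_row_decimal(table)
    recs = []
    for metric in METRIC_NAMES:
        want = str(printed[metric]).strip()
        got = computed[metric]
        got_str = "-" if got is None else str(got)
        recs.append(
            {
                "metric": metric,
                "printed": want,
                "recomputed": got_str,
                "match": (got_str == want) or (got is not None and Decimal(want) == got),
            }
        )
    report = pd.DataFrame(recs)
    if counts_csv is not None or metrics_csv is None:
        totals = datapoint_totals(load_datapoint_counts(counts_csv))
        report.attrs["datapoint_totals"] = totals
    return report
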