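"""Clinical diagnostic statistics against a pathological gold standard.

Two table layouts are supported: per-stage detection counts (TNM stage
label, number of gold-standard cases, number the modality assigned to that
stage), from which predicted positive rates (PPR) are computed; and a 2x2
resectability layout (TP/FN/TN/FP), from which sensitivity, specificity and
accuracy follow. Modalities are compared stage-by-stage with a Pearson
chi-square on the detected / not-detected 2x2 table (continuity-corrected),
falling back to Fisher's exact test when a margin is empty.

The tables printed in the source study (T/N/M staging and resectability for
gastrointestinal-filling contrast-enhanced ultrasound vs. enhanced CT, 102
gastric-cancer patients) ship as CSV fixtures under ``ceustrack.data``.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ContingencyTable",
    "DiagnosticSummary",
    "positive_rate",
    "binary_performance",
    "compare_modalities",
    "load_fixture",
    "summarize",
]


@dataclass
class ContingencyTable:
    """Either per-stage counts (``stages`` frame) or a 2x2 binary layout."""

    stages: pd.DataFrame | None = None  # columns: stage, gold_n, detected_n
    tp: int | None = None
    fn: int | None = None
    tn: int | None = None
    fp: int | None = None
    modality: str = ""

    @staticmethod
    def from_stage_rows(rows, modality: str = "") -> "ContingencyTable":
        df = pd.DataFrame(rows, columns=["stage", "gold_n", "detected_n"])
        if (df[["gold_n", "detected_n"]] < 0).any().any():
            raise ValueError("counts must be nonnegative")
        return ContingencyTable(stages=df, modality=modality)

    @staticmethod
    def from_binary(tp: int, fn: int, tn: int, fp: int, modality: str = "") -> "ContingencyTable":
        for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a nonnegative integer")
        return ContingencyTable(tp=int(tp), fn=int(fn), tn=int(tn), fp=int(fp), modality=modality)

    @property
    def is_binary(self) -> bool:
        return self.tp is not None


@dataclass
class DiagnosticSummary:
    ppr: dict | None = None  # stage -> percent
    sensitivity: float | None = None
    specificity: float | None = None
    accuracy: float | None = None
    chi2: float | None = None
    p_value: float | None = None
    exact_fallback: bool = False

    def to_dict(self) -> dict:
        out = {}
        if self.ppr is not None:
            out["ppr"] = self.ppr
        for k in ("sensitivity", "specificity", "accuracy", "chi2", "p_value"):
            v = getattr(self, k)
            if v is not None:
                out[k] = v
        if self.exact_fallback:
            out["exact_fallback"] = True
        return out


def positive_rate(gold_n: int, detected_n: int) -> float:
    """Predicted positive rate in percent, rounded to 2 decimals.

    The denominator is the number of gold-standard cases of the stage; the
    numerator is how many of them the modality assigned to that stage.
    """
    if gold_n < 1:
        raise ValueError("gold_n must be >= 1")
    if detected_n < 0:
        raise ValueError("detected_n must be nonnegative")
    if detected_n > gold_n:
        raise ValueError(f"detected_n ({detected_n}) exceeds gold_n ({gold_n})")
    return round(100.0 * detected_n / gold_n, 2)


def binary_performance(tp: int, fn: int, tn: int, fp: int) -> tuple[float, float, float]:
    """(sensitivity, specificity, accuracy) in percent at 2 decimals."""
    for name, v in (("tp", tp), ("fn", fn), ("tn", tn), ("fp", fp)):
        if v < 0:
            raise ValueError(f"{name} must be nonnegative")
    if tp + fn < 1:
        raise ValueError("no positive-class cases (tp + fn = 0)")
    if tn + fp < 1:
        raise ValueError("no negative-class cases (tn + fp = 0)")
    sens = round(100.0 * tp / (tp + fn), 2)
    spec = round(100.0 * tn / (tn + fp), 2)
    acc = round(100.0 * (tp + tn) / (tp + fn + tn + fp), 2)
    return sens, spec, acc


def compare_modalities(
    table_a: ContingencyTable, table_b: ContingencyTable, stage: str | None = None
) -> tuple[float, float, bool]:
    """Chi-square comparison of two modalities' detection of one stage.

    Builds the detected / not-detected x modality 2x2 table and applies the
    continuity-corrected Pearson chi-square (1 df). When any margin is zero
    the chi-square is undefined and Fisher's exact test is used instead;
    the returned flag is True in that case (chi2 reported as NaN).

    Returns ``(chi2, p, exact_fallback)``.
    """
    def counts(tbl: ContingencyTable) -> tuple[int, int]:
        if tbl.is_binary:
            raise ValueError("compare_modalities expects per-stage tables")
        df = tbl.stages
        if stage is not None:
            df = df[df["stage"] == stage]
            if df.empty:
                raise ValueError(f"stage {stage!r} not in table")
        gold = int(df["gold_n"].sum())
        det = int(df["detected_n"].sum())
        return det, gold - det

    a_det, a_miss = counts(table_a)
    b_det, b_miss = counts(table_b)
    if (a_det + a_miss) != (b_det + b_miss):
        raise ValueError("modalities were scored against different gold totals")
    obs = np.array([[a_det, a_miss], [b_det, b_miss]])
    if (obs.sum(axis=0) == 0).any() or (obs.sum(axis=1) == 0).any():
        p = stats.fisher_exact(obs)[1]
        return float("nan"), float(p), True
    chi2, p, _, _ = stats.chi2_contingency(obs, correction=True)
    return float(chi2), float(p), False


def summarize(table: ContingencyTable) -> DiagnosticSummary:
    """Per-stage PPRs, or sensitivity/specificity/accuracy for a 2x2 table."""
    if table.is_binary:
        sens, spec, acc = binary_performance(table.tp, table.fn, table.tn, table.fp)
        return DiagnosticSummary(sensitivity=sens, specificity=spec, accuracy=acc)
    ppr = {
        str(r.stage): positive_rate(int(r.gold_n), int(r.detected_n))
        for r in table.stages.itertuples(index=False)
    }
    return DiagnosticSummary(ppr=ppr)


# ---------------------------------------------------------------------------
# shipped study tables
# ---------------------------------------------------------------------------

_DATA = resources.files("ceustrack.data")


def load_fixture(name: str, modality: str | None = None) -> ContingencyTable:
    """Load a shipped study table.

    ``name`` is one of ``"staging"`` (per-stage counts for both modalities;
    pass ``modality="CEUS"`` or ``"CT"``) or ``"resectability"`` (2x2 layout
    per modality; ``modality`` required).
    """
    if name == "staging":
        df = pd.read_csv(_DATA / "staging_counts.csv")
        if modality is not None:
            df = df[df["modality"] == modality].drop(columns=["modality"])
            if df.empty:
                raise ValueError(f"unknown modality {modality!r}")
            return ContingencyTable(stages=df.reset_index(drop=True), modality=modality)
        return ContingencyTable(stages=df)
    if name == "resectability":
        df = pd.read_csv(_DATA / "resectability_counts.csv")
        row = df[df["modality"] == modality]
        if row.empty:
            raise ValueError(f"unknown modality {modality!r}")
        r = row.iloc[0]
        return ContingencyTable.from_binary(
            int(r.tp), int(r.fn), int(r.tn), int(r.fp), modality=modality
        )
    raise ValueError(f"unknown fixture {name!r}")


def read_counts_csv(path: str | Path) -> list[ContingencyTable]:
    """Read a user counts CSV in either supported layout.

    ``stage,modality,gold_n,detected_n`` rows give one per-stage table per
    modality; ``modality,tp,fn,tn,fp`` rows give one 2x2 table per modality.
    """
    df = pd.read_csv(path)
    cols = set(df.columns)
    tables = []
    if {"stage", "modality", "gold_n", "detected_n"} <= cols:
        for modality, grp in df.groupby("modality", sort=False):
            tables.append(
                ContingencyTable(
                    stages=grp[["stage", "gold_n", "detected_n"]].reset_index(drop=True),
                    modality=str(modality),
                )
            )
    elif {"modality", "tp", "fn", "tn", "fp"} <= cols:
        for r in df.itertuples(index=False):
            tables.append(
                ContingencyTable.from_binary(
                    int(r.tp), int(r.fn), int(r.tn), int(r.fp), modality=str(r.modality)
                )
            )
    else:
        raise ValueError(f"unrecognized counts layout: columns {sorted(cols)}")
    return tables
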