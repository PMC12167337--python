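"""Reader-study statistics for the dual-modality morphology experiment.

Three blinded readers measured fracture angulation on fused POCUS views
and on the matched lateral X-rays of the same 11 wrists, and classified
each as buckle (B), greenstick (G) or no fracture (N).  This module
reproduces the derived statistics from the raw readings:

* per-sample reference angulation — the mean of the three X-ray readings;
* per-reader, per-modality mean absolute error (MAE) against the
  reference, excluding samples whose reference is "no fracture";
* the mean POCUS-minus-X-ray MAE discrepancy across readers;
* the Pearson correlation between pooled POCUS absolute errors and the
  reference angulations;
* mean classification accuracy per modality, and majority-vote ground
  truth labels.

Conventions (they reproduce the printed statistics and are applied
uniformly): a "no fracture" reading counts as 0.0 deg wherever a number
is needed, and references are rounded to one decimal before any error is
computed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "ReadingTable",
    "StudyReport",
    "load_bundled_readings",
    "reference_angulation",
    "mae",
    "mean_discrepancy",
    "pooled_pearson",
    "mean_accuracy",
    "majority_vote",
    "compute_report",
]

PARTICIPANTS = (1, 2, 3)
MODALITIES = ("POCUS", "X-ray")

#: sentinel for "reader called the sample non-fractured" (printed as a dash)
NO_FRACTURE = None


def _norm_modality(m: str) -> str:
    m = str(m).strip().lower().replace("-", "").replace("_", "")
    if m == "pocus":
        return "POCUS"
    if m in ("xray", "x"):
        return "X-ray"
    raise ValueError(f"unknown modality {m!r}")


@dataclass(frozen=True)
class ReadingTable:
    """Raw per-sample, per-participant, per-modality angulation readings.

    ``readings`` holds one row per (sample, participant, modality) with an
    ``angle_deg`` column where NaN encodes the no-fracture marker.
    ``accuracies`` (optional) holds per-participant classification
    accuracies per modality.
    """

    readings: pd.DataFrame
    accuracies: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        df = self.readings
        required = {"sample", "participant", "modality", "angle_deg"}
        if not required.issubset(df.columns):
            raise ValueError(f"readings need columns {sorted(required)}")
        df = df.copy()
        df["modality"] = df["modality"].map(_norm_modality)
        df["participant"] = df["participant"].astype(int)
        object.__setattr__(self, "readings", df)
        got_p = set(df["participant"].unique())
        if got_p != set(PARTICIPANTS):
            raise ValueError(f"expected participants {PARTICIPANTS}, got {sorted(got_p)}")
        if set(df["modality"].unique()) != set(MODALITIES):
            raise ValueError("expected both POCUS and X-ray readings")
        dup = df.duplicated(["sample", "participant", "modality"])
        if dup.any():
            raise ValueError("duplicate (sample, participant, modality) rows")

    @classmethod
    def from_csv(cls, path, accuracies_path=None) -> "ReadingTable":
        df = pd.read_csv(path)
        for i, row in df.iterrows():
            if "modality" not in df.columns:
                break
            try:
                _norm_modality(row["modality"])
            except ValueError as e:
                raise ValueError(f"{path}: row {i + 2}: {e}") from e
        acc = pd.read_csv(accuracies_path) if accuracies_path is not None else None
        if acc is not None:
            acc = acc.copy()
            acc["modality"] = acc["modality"].map(_norm_modality)
        return cls(readings=df, accuracies=acc)

    @property
    def samples(self) -> list:
        return sorted(self.readings["sample"].unique())

    def angle(self, sample, participant: int, modality: str) -> float | None:
        """Reading in degrees, or NO_FRACTURE for the dash marker."""
        df = self.readings
        row = df[
            (df["sample"] == sample)
            & (df["participant"] == participant)
            & (df["modality"] == _norm_modality(modality))
        ]
        if len(row) != 1:
            raise KeyError(f"no reading for sample={sample}, participant={participant}, {modality}")
        v = row["angle_deg"].iloc[0]
        return NO_FRACTURE if pd.isna(v) else float(v)


def load_bundled_readings() -> ReadingTable:
    """The packaged fixture of the 11-sample, 3-reader study."""
    pkg = resources.files("pocusalign.data")
    with resources.as_file(pkg / "table2_readings.csv") as rp, resources.as_file(
        pkg / "table1_accuracy.csv"
    ) as ap:
        return ReadingTable.from_csv(rp, accuracies_path=ap)


def load_bundled_gt_labels() -> dict:
    with resources.as_file(resources.files("pocusalign.data") / "table1_gt_labels.json") as p:
        with open(p) as fh:
            return {k: v for k, v in json.load(fh)["labels"].items()}


# ---------------------------------------------------------------------------
# statistics


def reference_angulation(tbl: ReadingTable) -> dict:
    """Per-sample reference: mean of the three X-ray readings, one decimal.

    No-fracture readings count as 0.0 deg; a sample where all three X-ray
    readings are no-fracture keeps the no-fracture marker (None).
    """
    refs: dict = {}
    for s in tbl.samples:
        vals = [tbl.angle(s, p, "X-ray") for p in PARTICIPANTS]
        if all(v is NO_FRACTURE for v in vals):
            refs[s] = NO_FRACTURE
        else:
            refs[s] = round(sum(0.0 if v is None else v for v in vals) / len(vals), 1)
    return refs


def _fracture_samples(refs: dict) -> list:
    return [s for s, r in refs.items() if r is not NO_FRACTURE]


def mae(tbl: ReadingTable, refs: dict | None = None) -> dict:
    """MAE per (participant, modality) over fracture-reference samples."""
    refs = refs if refs is not None else reference_angulation(tbl)
    frac = _fracture_samples(refs)
    out = {}
    for p in PARTICIPANTS:
        for m in MODALITIES:
            errs = [abs((tbl.angle(s, p, m) or 0.0) - refs[s]) for s in frac]
            out[(p, m)] = round(float(np.mean(errs)), 1)
    return out


def mean_discrepancy(maes: dict) -> float:
    """Mean over participants of (MAE_POCUS - MAE_X-ray), one decimal."""
    missing = [(p, m) for p in PARTICIPANTS for m in MODALITIES if (p, m) not in maes]
    if missing:
        raise ValueError(f"missing MAE entries: {missing}")
    return round(float(np.mean([maes[(p, "POCUS")] - maes[(p, "X-ray")] for p in PARTICIPANTS])), 1)


def pooled_pearson(tbl: ReadingTable, refs: dict | None = None) -> float:
    """Pearson r between pooled POCUS absolute errors and the references.

    Errors from all three participants over the fracture-reference samples
    are pooled into one vector, paired with the (repeated) reference
    angulations.
    """
    refs = refs if refs is not None else reference_angulation(tbl)
    frac = _fracture_samples(refs)
    errs, rvals = [], []
    for p in PARTICIPANTS:
        for s in frac:
            errs.append(abs((tbl.angle(s, p, "POCUS") or 0.0) - refs[s]))
            rvals.append(refs[s])
    if len(set(rvals)) < 2:
        raise ValueError("need >= 2 distinct reference values")
    if float(np.std(errs)) < 1e-12:
        raise ValueError("zero variance in absolute errors; correlation undefined")
    return float(np.corrcoef(errs, rvals)[0, 1])


def mean_accuracy(tbl: ReadingTable, modality: str) -> float:
    """Mean of the per-participant classification accuracies, two decimals."""
    if tbl.accuracies is None:
        raise ValueError("reading table carries no per-participant accuracies")
    m = _norm_modality(modality)
    acc = tbl.accuracies
    vals = acc.loc[acc["modality"] == m, "accuracy"].astype(float)
    if len(vals) != len(PARTICIPANTS):
        raise ValueError(f"expected {len(PARTICIPANTS)} accuracies for {m}, got {len(vals)}")
    return round(float(vals.mean()), 2)


def majority_vote(labels) -> str:
    """Label occurring at least twice among three {B, G, N} votes."""
    labels = list(labels)
    if len(labels) != 3 or any(l not in ("B", "G", "N") for l in labels):
        raise ValueError("expected three labels from {B, G, N}")
    for l in set(labels):
        if labels.count(l) >= 2:
            return l
    raise ValueError("no majority among labels " + ",".join(labels))


# ---------------------------------------------------------------------------
# report


@dataclass(frozen=True)
class StudyReport:
    references: dict
    mae: dict  # (participant, modality) -> degrees
    mean_discrepancy_deg: float
    pearson_r: float
    mean_accuracy_pocus: float | None
    mean_accuracy_xray: float | None

    def to_dict(self) -> dict:
        return {
            "references_deg": {
                str(s): (None if r is NO_FRACTURE else r) for s, r in self.references.items()
            },
            "mae_deg": {f"participant{p}_{m}": v for (p, m), v in self.mae.items()},
            "mean_discrepancy_deg": self.mean_discrepancy_deg,
            "pearson_r": round(self.pearson_r, 2),
            "mean_accuracy_pocus": self.mean_accuracy_pocus,
            "mean_accuracy_xray": self.mean_accuracy_xray,
        }


def compute_report(tbl: ReadingTable) -> StudyReport:
    """All study statistics from raw readings (and accuracies if present)."""
    refs = reference_angulation(tbl)
    maes = mae(tbl, refs)
    return StudyReport(
        references=refs,
        mae=maes,
        mean_discrepancy_deg=mean_discrepancy(maes),
        pearson_r=pooled_pearson(tbl, refs),
        mean_accuracy_pocus=mean_accuracy(tbl, "POCUS") if tbl.accuracies is not None else None,
        mean_accuracy_xray=mean_accuracy(tbl, "X-ray") if tbl.accuracies is not None else None,
    )
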