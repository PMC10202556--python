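"""Shared paths and loaders for the numbered analysis scripts."""

from __future__ import annotations

import pathlib

import numpy as np
import pandas as pd

from netphase.model import Cohort, read_cohort
from netphase.staging import PhaseAssignment

ROOT = pathlib.Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
COHORTS = RESULTS / "cohorts"

SEED = 1


def load_cohorts() -> dict[str, Cohort]:
    return {label: read_cohort(COHORTS / label, label=label)
            for label in ("HC", "TAU", "TDP")}


def load_phases(label: str) -> PhaseAssignment:
    df = pd.read_csv(RESULTS / f"phases_{label}.tsv", sep="\t")
    return PhaseAssignment(phases=df["phase"].to_numpy(dtype=int),
                           ratios=df["ratio"].to_numpy(dtype=float))


def load_atrophy(label: str):
    df = pd.read_csv(RESULTS / f"atrophy_{label}.tsv", sep="\t", index_col=0)
    return df.to_numpy(dtype=bool), list(df.index)


def load_truth(label: str) -> pd.DataFrame:
    return pd.read_csv(RESULTS / f"truth_{label}.tsv", sep="\t")
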