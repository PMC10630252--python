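"""Cohort descriptive statistics and the pipeline configuration object."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import pandas as pd
import yaml

from .io import SampleSheet
from .qc import QCParams
from .regions import RegionParams
from .sitetest import SignificanceParams


def load_study_cohort() -> SampleSheet:
    """The bundled SETD1A / SETD2 NDD study cohort sample sheet.

    Sixteen individuals with germline variants in the SETD1A or SETD2
    lysine methyltransferase genes (ages at DNA sampling, sex and HGVS
    coding-variant labels), grouped by variant class.  Useful as a
    worked example for the cohort summary operations.
    """
    from importlib.resources import files

    path = files("episign.data").joinpath("chromatin_ndd_cohort.tsv")
    df = pd.read_csv(path, sep="\t", dtype={"id": str}, keep_default_na=False)
    return SampleSheet(df)


def _round_half_up(x: float, ndigits: int = 1) -> float:
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class CohortSummary:
    per_group: pd.DataFrame  # group, n, mean_age, n_male, n_female
    recurrent_variants: dict[str, int]  # label -> multiplicity (>= 2 only)

    @property
    def n_recurrent(self) -> int:
        return len(self.recurrent_variants)


def summarize_cohort(sheet: SampleSheet) -> CohortSummary:
    """Per-group n / mean age (half-up, 1 decimal) / sex counts + recurrent variants.

    A variant label is recurrent when the exact same non-empty string
    appears for two or more samples (no HGVS normalization).
    """
    df = sheet.frame
    if len(df) == 0:
        raise ValueError("empty sample sheet")
    rows = []
    for group, sub in df.groupby("group", sort=True):
        ages = sub["age"].dropna()
        rows.append(
            {
                "group": group,
                "n": len(sub),
                "mean_age": _round_half_up(float(ages.mean()), 1) if len(ages) else float("nan"),
                "n_male": int((sub["sex"].astype(str).str.upper() == "M").sum()),
                "n_female": int((sub["sex"].astype(str).str.upper() == "F").sum()),
            }
        )
    counts = df.loc[df["variant"] != "", "variant"].value_counts()
    recurrent = {str(k): int(v) for k, v in counts.items() if v >= 2}
    return CohortSummary(pd.DataFrame(rows), recurrent)


@dataclass
class PipelineConfig:
    """Everything a discovery or calibration run needs, YAML-serializable."""

    coverage_dir: str = ""
    sample_sheet: str = ""
    islands_bed: str = ""
    snp_mask_bed: str = ""
    targets_bed: str = ""
    genes_bed: str = ""
    celltype_reference: str = ""
    output_dir: str = "episign_out"
    seed: int = 0
    control_group: str = "control"
    qc: QCParams = field(default_factory=QCParams)
    significance: SignificanceParams = field(default_factory=SignificanceParams)
    region: RegionParams = field(default_factory=RegionParams)
    adjust_celltype: bool = False
    adjust_sva: bool = False
    covariates: tuple = ()
    nonredundant_cutoff: float = 0.90
    gomlom_threshold: float = 3.0
    calibration_k_max: int = 15
    calibration_reps: int = 20

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        for key, klass in (("qc", QCParams), ("significance", SignificanceParams), ("region", RegionParams)):
            if key in kwargs and isinstance(kwargs[key], dict):
                sub = dict(kwargs[key])
                if key == "qc" and "sex_chroms" in sub:
                    sub["sex_chroms"] = frozenset(sub["sex_chroms"])
                kwargs[key] = klass(**sub)
        if "covariates" in kwargs:
            kwargs["covariates"] = tuple(kwargs["covariates"])
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["qc"]["sex_chroms"] = sorted(d["qc"]["sex_chroms"])
        d["covariates"] = list(d["covariates"])
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]
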