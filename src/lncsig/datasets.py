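"""In-memory containers and text I/O for count panels.

Counts live in a pandas DataFrame (samples x probes, nonnegative integers)
aligned row-wise with a metadata DataFrame of per-sample records (cohort
label, pathology grade, absorbances, binding density, Cq values, clinical
covariates, optional external signature scores).  The panel maps each count
column to its probe class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import ProbePanel, PROBE_CLASSES

#: Metadata columns recognised throughout the pipeline.  Optional columns may
#: be absent; QC treats missing QC inputs as "not assessable".
METADATA_COLUMNS = (
    "cohort", "grade",
    "absorbance_414", "absorbance_541", "absorbance_576",
    "binding_density", "cq_gnas", "cq_vim", "amplification_failed",
    "jaundice", "main_duct", "mural_nodule", "gender_male",
    "cyst_size_cm", "ca19_9", "albumin", "hrs", "wf",
    "mirna_score", "radiomic_score",
)

GRADES = ("none", "low", "moderate", "high", "invasive")
BENIGN_GRADES = frozenset({"low", "moderate"})
MALIGNANT_GRADES = frozenset({"high", "invasive"})


@dataclass
class CountDataset:
    """Raw nCounter-style counts plus aligned per-sample metadata."""

    counts: pd.DataFrame
    metadata: pd.DataFrame
    panel: ProbePanel

    def __post_init__(self) -> None:
        if not self.counts.index.equals(self.metadata.index):
            raise ValueError("counts and metadata sample indexes differ")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = [p for p in self.counts.columns if p not in self.panel]
        if missing:
            raise ValueError(f"probes absent from panel: {missing}")
        if "grade" in self.metadata and "cohort" in self.metadata:
            ctrl = self.metadata["cohort"].eq("control")
            bad = (self.metadata["grade"].eq("none") != ctrl)
            if bad.any():
                raise ValueError(
                    "grade must be 'none' exactly for control samples; "
                    f"offending samples: {list(self.metadata.index[bad])[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.counts)

    def subset(self, sample_ids) -> "CountDataset":
        """Pure row filter; counts of retained samples are untouched."""
        return CountDataset(
            counts=self.counts.loc[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
            panel=self.panel,
        )

    def malignancy_labels(self) -> pd.Series:
        """Boolean malignant indicator for case samples (benign = low/moderate
        dysplasia, malignant = high-grade/invasive)."""
        cases = self.metadata[self.metadata["cohort"] == "case"]
        return cases["grade"].isin(MALIGNANT_GRADES)

    # -- text I/O -----------------------------------------------------------

    def to_csv(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.counts.to_csv(out / "counts.csv", index_label="sample_id")
        self.metadata.to_csv(out / "metadata.csv", index_label="sample_id")
        with open(out / "panel.json", "w") as fh:
            json.dump(self.panel.classes, fh, indent=1)

    @classmethod
    def from_csv(
        cls,
        counts_path: str | Path,
        metadata_path: str | Path,
        panel: ProbePanel | str | Path,
    ) -> "CountDataset":
        counts = pd.read_csv(counts_path, index_col="sample_id")
        metadata = pd.read_csv(metadata_path, index_col="sample_id")
        if not isinstance(panel, ProbePanel):
            with open(panel) as fh:
                panel = ProbePanel(json.load(fh))
        return cls(counts=counts, metadata=metadata, panel=panel)


@dataclass
class NormalizedMatrix:
    """Background-corrected, housekeeping-normalized log2 abundance.

    Attributes
    ----------
    data
        samples x retained endogenous probes, log2 units, finite.
    cutpoints
        Per-sample negative-control background cut-point (mean + 2 SD),
        count units.
    scale_factors
        Per-sample housekeeping scale factor f_s = G / g_s.
    reference_geomean
        Cohort reference G: arithmetic mean over samples of the per-sample
        housekeeping geometric means, count units.
    retained_probes
        Endogenous probes passing the 20% detection filter.
    """

    data: pd.DataFrame
    cutpoints: pd.Series
    scale_factors: pd.Series
    reference_geomean: float
    retained_probes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not np.isfinite(self.data.to_numpy(dtype=float)).all():
            raise ValueError("normalized log2 values must be finite")

    def provenance(self) -> dict:
        return {
            "retained_probes": list(self.retained_probes),
            "reference_geomean": float(self.reference_geomean),
            "cutpoints": {k: float(v) for k, v in self.cutpoints.items()},
            "scale_factors": {k: float(v) for k, v in self.scale_factors.items()},
        }


def read_rcc(path: str | Path) -> tuple[pd.Series, dict]:
    """Parse one nCounter RCC reporter file (a sectioned CSV dialect).

    Returns the probe counts (indexed by gene name, with the probe class
    from the CodeClass column attached via ``counts.attrs['code_class']``)
    and the lane attributes dict, from which ``BindingDensity`` is read.
    Only the ``Code_Summary`` and ``Lane_Attributes`` sections are consumed.
    """
    section = None
    lane: dict[str, str] = {}
    names: list[str] = []
    classes: list[str] = []
    values: list[int] = []
    header_skipped = False
    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            continue
        if line.startswith("<") and line.endswith(">"):
            tag = line.strip("<>")
            section = None if tag.startswith("/") else tag
            header_skipped = False
            continue
        fields = line.split(",")
        if section == "Lane_Attributes" and len(fields) >= 2:
            lane[fields[0]] = fields[1]
        elif section == "Code_Summary":
            if not header_skipped:
                header_skipped = True  # CodeClass,Name,Accession,Count
                continue
            if len(fields) >= 4:
                classes.append(fields[0])
                names.append(fields[1])
                values.append(int(round(float(fields[3]))))
    counts = pd.Series(values, index=names, name="count")
    counts.attrs["code_class"] = dict(zip(names, classes))
    return counts, lane


__all__ = [
    "CountDataset", "NormalizedMatrix", "read_rcc",
    "METADATA_COLUMNS", "GRADES", "BENIGN_GRADES", "MALIGNANT_GRADES",
    "PROBE_CLASSES",
]
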