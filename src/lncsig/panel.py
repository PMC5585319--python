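"""Probe panel definitions for an nCounter-style plasma lncRNA assay.

A :class:`ProbePanel` assigns every probe (column of a count matrix) to a
functional class.  The class drives which QC and normalization rule consumes
it: endogenous probes are the analytes; negative controls define the
per-sample background cut-point; housekeeping genes define the scale factors;
spike-ins, hemolysis (erythrocyte) markers and WBC markers are carried
through for contamination assessment only.
"""

from __future__ import annotations

from dataclasses import dataclass, field


ENDOGENOUS = "endogenous"
NEGATIVE = "negative"
POSITIVE = "positive"
HOUSEKEEPING = "housekeeping"
SPIKE_IN = "spike_in"
HEMOLYSIS_MARKER = "hemolysis_marker"
WBC_MARKER = "wbc_marker"

PROBE_CLASSES = (
    ENDOGENOUS,
    NEGATIVE,
    POSITIVE,
    HOUSEKEEPING,
    SPIKE_IN,
    HEMOLYSIS_MARKER,
    WBC_MARKER,
)

#: The 28 candidate plasma lncRNAs of the IPMN panel.
DEFAULT_LNCRNAS = (
    "ADARB2-AS1", "ANRIL", "AS1DHRS4", "BCYRN1", "DDX6P", "GAS5",
    "GLIS3-AS1", "H19", "HOTAIR", "HOTTIP", "HOXD-AS1", "HULC",
    "LINC00244", "LINC00469", "LINC00472", "LINC00491", "lncRNA-p21",
    "MALAT1", "MEG3", "PANDA", "PPP3CB", "PTENP1", "PVT1", "SRA",
    "TERC", "UCA1", "XIST", "aHIF",
)

DEFAULT_HOUSEKEEPING = ("ACTB", "PGK1", "PPIB")
DEFAULT_SPIKE_INS = ("NEFL", "ENO2", "GFAP")
DEFAULT_HEMOLYSIS_MARKERS = ("MB", "NGB", "CYGB")
DEFAULT_WBC_MARKERS = ("APOE", "CD68", "CD2", "CD3")
DEFAULT_NEGATIVES = tuple(f"NEG_{c}" for c in "ABCDEF")
DEFAULT_POSITIVES = tuple(f"POS_{c}" for c in "ABCDEF")

#: Expected counts of the positive-control geometric ladder (4-fold steps),
#: mirroring the platform's POS_A..POS_F titration.  Plumbing only: the
#: pipeline reports but never scales by positive controls.
POSITIVE_LADDER = (8192, 2048, 512, 128, 32, 8)


@dataclass(frozen=True)
class ProbePanel:
    """Mapping from probe name to functional probe class.

    Parameters
    ----------
    classes
        Dict probe name -> one of :data:`PROBE_CLASSES`.
    """

    classes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        bad = {c for c in self.classes.values() if c not in PROBE_CLASSES}
        if bad:
            raise ValueError(f"unknown probe classes: {sorted(bad)}")

    def probes(self, probe_class: str) -> list[str]:
        """Names of all probes of the given class, in panel order."""
        if probe_class not in PROBE_CLASSES:
            raise ValueError(f"unknown probe class: {probe_class!r}")
        return [p for p, c in self.classes.items() if c == probe_class]

    @property
    def endogenous(self) -> list[str]:
        return self.probes(ENDOGENOUS)

    @property
    def negatives(self) -> list[str]:
        return self.probes(NEGATIVE)

    @property
    def housekeeping(self) -> list[str]:
        return self.probes(HOUSEKEEPING)

    @property
    def hemolysis_markers(self) -> list[str]:
        return self.probes(HEMOLYSIS_MARKER)

    @property
    def wbc_markers(self) -> list[str]:
        return self.probes(WBC_MARKER)

    @property
    def all_probes(self) -> list[str]:
        return list(self.classes)

    def __contains__(self, probe: str) -> bool:
        return probe in self.classes

    def __len__(self) -> int:
        return len(self.classes)


def default_panel(endogenous: tuple[str, ...] = DEFAULT_LNCRNAS) -> ProbePanel:
    """The standard panel: endogenous lncRNAs plus all built-in controls."""
    classes: dict[str, str] = {}
    for p in endogenous:
        classes[p] = ENDOGENOUS
    for p in DEFAULT_HOUSEKEEPING:
        classes[p] = HOUSEKEEPING
    for p in DEFAULT_SPIKE_INS:
        classes[p] = SPIKE_IN
    for p in DEFAULT_HEMOLYSIS_MARKERS:
        classes[p] = HEMOLYSIS_MARKER
    for p in DEFAULT_WBC_MARKERS:
        classes[p] = WBC_MARKER
    for p in DEFAULT_NEGATIVES:
        classes[p] = NEGATIVE
    for p in DEFAULT_POSITIVES:
        classes[p] = POSITIVE
    return ProbePanel(classes)
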