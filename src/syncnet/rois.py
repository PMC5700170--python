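"""Region-of-interest (ROI) vocabulary and label utilities.

Electrodes are assigned to atlas-based cortical/subcortical labels, 37 per
hemisphere (74 total), written as ``"L-<name>"`` / ``"R-<name>"``.  The
default vocabulary below is a standard Talairach-daemon-style gyrus list; any
other vocabulary with the same hemisphere-prefix convention may be supplied
wherever a ``vocabulary`` argument is accepted.
"""

from __future__ import annotations

from math import comb

# 37 base labels per hemisphere.
BASE_LABELS: tuple[str, ...] = (
    # frontal
    "superior-frontal",
    "middle-frontal",
    "inferior-frontal",
    "medial-frontal",
    "orbital",
    "rectal",
    "precentral",
    "paracentral",
    "subcallosal",
    # limbic / cingulate
    "anterior-cingulate",
    "cingulate",
    "posterior-cingulate",
    # medial temporal
    "parahippocampal",
    "uncus",
    "hippocampus",
    "amygdala",
    # lateral temporal
    "superior-temporal",
    "middle-temporal",
    "inferior-temporal",
    "transverse-temporal",
    "fusiform",
    # parietal
    "postcentral",
    "superior-parietal",
    "inferior-parietal",
    "supramarginal",
    "angular",
    "precuneus",
    # occipital
    "cuneus",
    "lingual",
    "superior-occipital",
    "middle-occipital",
    "inferior-occipital",
    # insula and subcortical
    "insula",
    "caudate",
    "putamen",
    "lentiform",
    "thalamus",
)

assert len(BASE_LABELS) == 37

_LOBE_OF: dict[str, str] = {}
for _name in BASE_LABELS[:9]:
    _LOBE_OF[_name] = "frontal"
for _name in BASE_LABELS[9:12]:
    _LOBE_OF[_name] = "limbic"
for _name in BASE_LABELS[12:16]:
    _LOBE_OF[_name] = "mtl"
for _name in BASE_LABELS[16:21]:
    _LOBE_OF[_name] = "temporal"
for _name in BASE_LABELS[21:27]:
    _LOBE_OF[_name] = "parietal"
for _name in BASE_LABELS[27:32]:
    _LOBE_OF[_name] = "occipital"
for _name in BASE_LABELS[32:33]:
    _LOBE_OF[_name] = "insula"
for _name in BASE_LABELS[33:]:
    _LOBE_OF[_name] = "subcortical"


def default_vocabulary() -> list[str]:
    """Full 74-label vocabulary: each base label prefixed with L-/R-."""
    return [f"{h}-{name}" for h in ("L", "R") for name in BASE_LABELS]


def hemisphere(label: str) -> str:
    """Hemisphere prefix ('L' or 'R') of a full ROI label."""
    h, _, rest = label.partition("-")
    if h not in ("L", "R") or not rest:
        raise ValueError(f"malformed ROI label: {label!r}")
    return h


def base_name(label: str) -> str:
    return label.partition("-")[2]


def lobe(label: str) -> str:
    """Broad region ('frontal', 'mtl', ...) a full label belongs to."""
    name = base_name(label)
    try:
        return _LOBE_OF[name]
    except KeyError:
        raise ValueError(f"unknown base label: {name!r}") from None


def is_interhemispheric(label_a: str, label_b: str) -> bool:
    return hemisphere(label_a) != hemisphere(label_b)


def n_roi_pairs(n_rois: int = 74) -> int:
    """Number of distinct unordered ROI pairs (diagonal excluded)."""
    return comb(n_rois, 2)
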