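"""Packaged dictionary of the 145 modeled brain regions of interest.

The modeled feature vector covers 145 anatomical ROI volumes (mm^3):
119 gray-matter regions, 20 white-matter regions and 6 ventricular
spaces.  Names follow a conventional multi-atlas parcellation naming
scheme (bilateral structures listed Right before Left); users whose
atlas export uses different label strings can remap columns at read
time via :func:`neurokde.io.read_cohort`'s ``rename`` argument.

The dictionary order is the canonical column order of every cohort
table this package reads or writes.
"""

from __future__ import annotations

GRAY = "gray"
WHITE = "white"
VENTRICLE = "ventricle"

#: Bilateral gray-matter structures (each contributes a Right and a Left ROI).
_GRAY_BILATERAL = [
    "Accumbens Area",
    "Amygdala",
    "Caudate",
    "Putamen",
    "Pallidum",
    "Thalamus Proper",
    "Hippocampus",
    "Parahippocampal Gyrus",
    "Entorhinal Area",
    "Fusiform Gyrus",
    "Inferior Temporal Gyrus",
    "Middle Temporal Gyrus",
    "Superior Temporal Gyrus",
    "Temporal Pole",
    "Transverse Temporal Gyrus",
    "Planum Polare",
    "Planum Temporale",
    "Angular Gyrus",
    "Supramarginal Gyrus",
    "Superior Parietal Lobule",
    "Precuneus",
    "Postcentral Gyrus",
    "Postcentral Gyrus Medial Segment",
    "Precentral Gyrus",
    "Precentral Gyrus Medial Segment",
    "Superior Frontal Gyrus",
    "Superior Frontal Gyrus Medial Segment",
    "Middle Frontal Gyrus",
    "Inferior Frontal Gyrus Opercular Part",
    "Inferior Frontal Gyrus Orbital Part",
    "Inferior Frontal Gyrus Triangular Part",
    "Frontal Pole",
    "Gyrus Rectus",
    "Medial Frontal Cortex",
    "Medial Orbital Gyrus",
    "Lateral Orbital Gyrus",
    "Anterior Orbital Gyrus",
    "Posterior Orbital Gyrus",
    "Supplementary Motor Cortex",
    "Subcallosal Area",
    "Central Operculum",
    "Frontal Operculum",
    "Parietal Operculum",
    "Anterior Cingulate Gyrus",
    "Middle Cingulate Gyrus",
    "Posterior Cingulate Gyrus",
    "Anterior Insula",
    "Posterior Insula",
    "Calcarine Cortex",
    "Cuneus",
    "Lingual Gyrus",
    "Occipital Pole",
    "Superior Occipital Gyrus",
    "Middle Occipital Gyrus",
    "Inferior Occipital Gyrus",
    "Occipital Fusiform Gyrus",
    "Basal Forebrain",
    "Cerebellum Exterior",
    "Ventral Diencephalon",
]

_GRAY_MIDLINE = ["Brain Stem"]

_WHITE_BILATERAL = [
    "Frontal White Matter",
    "Temporal White Matter",
    "Parietal White Matter",
    "Occipital White Matter",
    "Insular White Matter",
    "Cingulate White Matter",
    "Corona Radiata",
    "Internal Capsule",
    "External Capsule",
]

_WHITE_MIDLINE = ["Corpus Callosum Anterior", "Corpus Callosum Posterior"]

_VENTRICLES_LEADING = ["3rd Ventricle", "4th Ventricle"]
_VENTRICLES_BILATERAL = ["Inferior Lateral Ventricle", "Lateral Ventricle"]


def _bilateral(names: list[str]) -> list[str]:
    return [f"{side} {name}" for name in names for side in ("Right", "Left")]


def _build() -> tuple[list[str], dict[str, str]]:
    names: list[str] = []
    tissue: dict[str, str] = {}

    def add(block: list[str], cls: str) -> None:
        for n in block:
            names.append(n)
            tissue[n] = cls

    # Midline ventricles lead (matching the released table dialect), then
    # subcortical gray, remaining ventricles, brain stem, white matter and
    # cortical gray matter.
    add(_VENTRICLES_LEADING, VENTRICLE)
    add(_bilateral(_GRAY_BILATERAL[:7]), GRAY)          # deep gray nuclei
    add(_bilateral(_VENTRICLES_BILATERAL), VENTRICLE)
    add(_GRAY_MIDLINE, GRAY)
    add(_bilateral(_WHITE_BILATERAL), WHITE)
    add(_WHITE_MIDLINE, WHITE)
    add(_bilateral(_GRAY_BILATERAL[7:]), GRAY)          # cortex and cerebellum
    return names, tissue


#: Canonical ordered ROI names (length 145).
ROI_NAMES: list[str]
#: Tissue class per ROI name: "gray" | "white" | "ventricle".
TISSUE_CLASS: dict[str, str]
ROI_NAMES, TISSUE_CLASS = _build()

N_ROI = len(ROI_NAMES)

#: Demographic columns preceding the ROI block in every cohort table.
ID_COLUMN = "SampleID"
SEX_COLUMN = "Sex"
RACE_COLUMN = "Race"
AGE_COLUMN = "Age"
GROUP_COLUMN = "Group"
COGNITION_COLUMN = "Cognition"

SEXES = ("F", "M")
RACES = ("White", "Black", "Asian")
GROUPS = ("CN", "MCI", "AD")

#: The six sex-by-race strata, in canonical output order.
STRATA = tuple((sex, race) for sex in SEXES for race in RACES)


def tissue_counts() -> dict[str, int]:
    """Number of ROIs per tissue class."""
    counts = {GRAY: 0, WHITE: 0, VENTRICLE: 0}
    for name in ROI_NAMES:
        counts[TISSUE_CLASS[name]] += 1
    return counts


def roi_indices(tissue: str) -> list[int]:
    """Positions (in dictionary order) of the ROIs of one tissue class."""
    if tissue not in (GRAY, WHITE, VENTRICLE):
        raise ValueError(f"unknown tissue class: {tissue!r}")
    return [i for i, n in enumerate(ROI_NAMES) if TISSUE_CLASS[n] == tissue]
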