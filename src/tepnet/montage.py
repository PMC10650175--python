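"""10-10 electrode montage helpers: presets, left-right mirroring, macro areas.

In the 10-10 naming scheme odd indices are left-hemisphere, even indices are
right-hemisphere and a trailing ``z`` marks the midline.  Mirroring a label
swaps hemisphere (O1 <-> O2, F3 <-> F4, ...) and fixes the midline.
"""

from __future__ import annotations

import re

__all__ = [
    "MONTAGE_59",
    "MONTAGE_12",
    "montage_preset",
    "mirror_label",
    "mirror_map",
    "IPSI_FRONTAL_LEFT",
    "macro_area_map",
    "MACRO_AREAS",
]

# Full 59-channel scalp layout of the recording setup (extended 10-10,
# AFz serving as ground and therefore absent).
MONTAGE_59 = [
    "Fp1", "Fp2",
    "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT7", "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6", "FT8",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8",
    "O1", "Oz", "O2",
]

# Small symmetric layout covering all four macro areas; the default for
# quick synthetic studies and tests.
MONTAGE_12 = ["Fp1", "Fp2", "F3", "F4", "FC1", "FC2",
              "C3", "C4", "P3", "P4", "O1", "O2"]

_PRESETS = {"full59": MONTAGE_59, "small12": MONTAGE_12}

_LABEL_RE = re.compile(r"^([A-Za-z]+?)(z|\d+)$")


def montage_preset(name: str) -> list[str]:
    """Return a named montage preset ('full59' or 'small12')."""
    try:
        return list(_PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown montage preset {name!r}; "
                       f"available: {sorted(_PRESETS)}") from None


def mirror_label(label: str) -> str:
    """Left-right mirror of a 10-10 label (odd <-> even, midline fixed)."""
    m = _LABEL_RE.match(label)
    if not m:
        raise ValueError(f"cannot parse 10-10 label {label!r}")
    row, idx = m.groups()
    if idx == "z" or idx == "Z":
        return label
    n = int(idx)
    return f"{row}{n + 1 if n % 2 == 1 else n - 1}"


def mirror_map(labels: list[str]) -> dict[str, str]:
    """Mirror map restricted to a montage; rejects asymmetric montages.

    Raises
    ------
    ValueError
        If any lateral label lacks its mirrored counterpart in the montage,
        listing the unpaired labels.
    """
    present = set(labels)
    mapping = {}
    unpaired = []
    for lab in labels:
        mir = mirror_label(lab)
        if mir not in present:
            unpaired.append(lab)
        mapping[lab] = mir
    if unpaired:
        raise ValueError(f"montage is not left-right symmetric; unpaired: {unpaired}")
    return mapping


# Frontal electrodes ipsilateral to a left-hemisphere stimulation site.
IPSI_FRONTAL_LEFT = ["Fp1", "AF7", "AF3", "F7", "F5", "F3", "F1",
                     "FT7", "FC5", "FC3", "FC1"]

# Anterior row -> posterior counterpart used to construct the occipital
# areas by front-back symmetry from the frontal list.
_FRONT_TO_BACK = {"Fp": "O", "AF": "PO", "F": "P", "FT": "TP", "FC": "CP"}

MACRO_AREAS = (
    "ipsilateral-frontal",
    "contralateral-frontal",
    "ipsilateral-occipital",
    "contralateral-occipital",
)


def _posterior_counterpart(label: str) -> str:
    m = _LABEL_RE.match(label)
    row, idx = m.groups()
    return f"{_FRONT_TO_BACK[row]}{idx}"


def macro_area_map(labels: list[str], stim_hemisphere: str = "left") -> dict[str, str]:
    """Assign montage labels to the four macro areas.

    The ipsilateral-frontal list is the published one; the remaining three
    areas are its mirror (contralateral-frontal) and front-back counterparts
    (occipital areas).  Electrodes outside the four lists are unassigned and
    omitted from the returned mapping.

    Parameters
    ----------
    labels : list of str
        The montage.
    stim_hemisphere : {"left", "right"}
        Hemisphere of the stimulation site ("left" for O1).
    """
    if stim_hemisphere not in {"left", "right"}:
        raise ValueError("stim_hemisphere must be 'left' or 'right'")
    ipsi_front = list(IPSI_FRONTAL_LEFT)
    contra_front = [mirror_label(l) for l in ipsi_front]
    ipsi_occ = [_posterior_counterpart(l) for l in ipsi_front]
    contra_occ = [mirror_label(l) for l in ipsi_occ]
    if stim_hemisphere == "right":
        ipsi_front, contra_front = contra_front, ipsi_front
        ipsi_occ, contra_occ = contra_occ, ipsi_occ
    present = set(labels)
    mapping: dict[str, str] = {}
    for area, lst in zip(
        MACRO_AREAS, (ipsi_front, contra_front, ipsi_occ, contra_occ)
    ):
        for lab in lst:
            if lab in present:
                mapping[lab] = area
    return mapping
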