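"""Default gray-matter parcellation table.

A 114-region table in the style of volumetric gray-matter atlases used for
structural covariance work: 56 bilateral structure pairs (left/right
homologues) plus two midline structures, each assigned to one of seven lobar
groups (frontal, parietal, temporal, occipital, limbic, insula, subcortical).
It lets the whole pipeline run at realistic dimensionality without any atlas
volume; smaller tables for desk tests are produced with ``n_pairs``.
"""

from __future__ import annotations

import pandas as pd

from .io import validate_regions

# (abbrev, full name, lobe) for the bilateral structures
_BILATERAL: list[tuple[str, str, str]] = [
    # frontal
    ("PrG", "Precentral gyrus", "frontal"),
    ("MPrG", "Precentral gyrus medial segment", "frontal"),
    ("SFG", "Superior frontal gyrus", "frontal"),
    ("MSFG", "Superior frontal gyrus medial segment", "frontal"),
    ("MFG", "Middle frontal gyrus", "frontal"),
    ("OpIFG", "Opercular part of the inferior frontal gyrus", "frontal"),
    ("OrIFG", "Orbital part of the inferior frontal gyrus", "frontal"),
    ("TrIFG", "Triangular part of the inferior frontal gyrus", "frontal"),
    ("AOrG", "Anterior orbital gyrus", "frontal"),
    ("POrG", "Posterior orbital gyrus", "frontal"),
    ("LOrG", "Lateral orbital gyrus", "frontal"),
    ("MOrG", "Medial orbital gyrus", "frontal"),
    ("SMC", "Supplementary motor cortex", "frontal"),
    ("FRP", "Frontal pole", "frontal"),
    ("GRe", "Gyrus rectus", "frontal"),
    ("CO", "Central operculum", "frontal"),
    # parietal
    ("PoG", "Postcentral gyrus", "parietal"),
    ("MPoG", "Postcentral gyrus medial segment", "parietal"),
    ("SPL", "Superior parietal lobule", "parietal"),
    ("SMG", "Supramarginal gyrus", "parietal"),
    ("AnG", "Angular gyrus", "parietal"),
    ("PCu", "Precuneus", "parietal"),
    ("PO", "Parietal operculum", "parietal"),
    # temporal
    ("STG", "Superior temporal gyrus", "temporal"),
    ("MTG", "Middle temporal gyrus", "temporal"),
    ("ITG", "Inferior temporal gyrus", "temporal"),
    ("TMP", "Temporal pole", "temporal"),
    ("FuG", "Fusiform gyrus", "temporal"),
    ("PP", "Planum polare", "temporal"),
    ("PT", "Planum temporale", "temporal"),
    ("TTG", "Transverse temporal gyrus", "temporal"),
    # occipital
    ("MOG", "Middle occipital gyrus", "occipital"),
    ("IOG", "Inferior occipital gyrus", "occipital"),
    ("SOG", "Superior occipital gyrus", "occipital"),
    ("OCP", "Occipital pole", "occipital"),
    ("Calc", "Calcarine cortex", "occipital"),
    ("Cun", "Cuneus", "occipital"),
    ("LiG", "Lingual gyrus", "occipital"),
    ("OFuG", "Occipital fusiform gyrus", "occipital"),
    # limbic
    ("ACgG", "Anterior cingulate gyrus", "limbic"),
    ("MCgG", "Middle cingulate gyrus", "limbic"),
    ("PCgG", "Posterior cingulate gyrus", "limbic"),
    ("Ent", "Entorhinal area", "limbic"),
    ("PHG", "Parahippocampal gyrus", "limbic"),
    ("SCA", "Subcallosal area", "limbic"),
    ("Hip", "Hippocampus", "limbic"),
    ("Amy", "Amygdala", "limbic"),
    # insula
    ("AIns", "Anterior insula", "insula"),
    ("PIns", "Posterior insula", "insula"),
    # subcortical
    ("Thal", "Thalamus Proper", "subcortical"),
    ("Put", "Putamen", "subcortical"),
    ("Cau", "Caudate", "subcortical"),
    ("Pal", "Pallidum", "subcortical"),
    ("Acc", "Accumbens Area", "subcortical"),
    ("BasF", "Basal Forebrain", "subcortical"),
    ("VDC", "Ventral Diencephalon", "subcortical"),
]

_MIDLINE: list[tuple[str, str, str]] = [
    ("CVL15", "Cerebellar Vermal Lobules I-V", "subcortical"),
    ("CVL67", "Cerebellar Vermal Lobules VI-VII", "subcortical"),
]


def default_region_table(n_pairs: int | None = None,
                         include_midline: bool = True) -> pd.DataFrame:
    """Region table with ``n_pairs`` homologous pairs (default: all 56).

    The full table (56 pairs + 2 midline = 114 regions) matches the node count
    of the reference volumetric parcellation; pass a small ``n_pairs`` for
    quick fixtures.
    """
    pairs = _BILATERAL if n_pairs is None else _BILATERAL[:n_pairs]
    if n_pairs is not None and n_pairs > len(_BILATERAL):
        raise ValueError(f"at most {len(_BILATERAL)} bilateral pairs available")
    rows = []
    for abbrev, name, lobe in pairs:
        left, right = f"{abbrev}.L", f"{abbrev}.R"
        rows.append((left, f"{name} left", "L", lobe, right))
        rows.append((right, f"{name} right", "R", lobe, left))
    if include_midline:
        for abbrev, name, lobe in _MIDLINE:
            rows.append((abbrev, name, "midline", lobe, ""))
    table = pd.DataFrame(
        rows, columns=["region_id", "name", "hemisphere", "lobe", "homologue_id"])
    return validate_regions(table)
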