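"""Shipped study design: marker panel, population panel, language tree.

This module encodes the design of a 10-marker chromosome-3 STR survey of
30 ethnic-minority populations from China (1,538 individuals).  The
marker map positions and the three dated language-tree nodes are the
published design constants; the population panel is a synthetic stand-in
— population names and language-family affiliations follow the published
survey where recoverable, but the coordinates are approximate
representative locations and two Yunnan Tibeto-Burman populations are
plausible fillers, because the original sampling table was not deposited
in machine-readable form.  Sample sizes are chosen to match the survey's
scale: minimum 37 (Tu), maximum 95 (Zhuang), median 50, total 1,538.
"""

from __future__ import annotations

from .dataset import Marker, PopulationMeta

__all__ = [
    "STUDY_MARKERS",
    "STUDY_POPULATIONS",
    "LANGUAGE_GROUP",
    "DEFAULT_LANGUAGE_TREE",
    "STUDY_MISSINGNESS_CELLS",
]

#: The ten chromosome-3 STR markers with genetic-map positions in cM.
STUDY_MARKERS: list[Marker] = [
    Marker("D3S1297", 8.3),
    Marker("D3S1304", 22.3),
    Marker("D3S1263", 36.1),
    Marker("D3S1266", 52.6),
    Marker("D3S1285", 91.2),
    Marker("D3S1278", 129.7),
    Marker("D3S1292", 146.6),
    Marker("D3S1279", 169.6),
    Marker("D3S1614", 177.8),
    Marker("D3S1580", 207.7),
]

#: population -> language-group leaf of the default language tree.
LANGUAGE_GROUP: dict[str, str] = {
    # Sinitic
    "HanGansu": "Chinese",
    "HanShandong": "Chinese",
    "HanGuangdong": "Chinese",
    # Tibeto-Burman (Sino-Tibetan)
    "Drung": "TibetoBurman",
    "Nu": "TibetoBurman",
    "Lisu": "TibetoBurman",
    "Tibetan": "TibetoBurman",
    "Yi": "TibetoBurman",
    "Bai": "TibetoBurman",
    "Pumi": "TibetoBurman",
    "Aini": "TibetoBurman",
    "Jinuo": "TibetoBurman",
    "Lahu": "TibetoBurman",
    "Naxi": "TibetoBurman",
    # Tai-Kadai
    "Li": "TaiKadai",
    "Mulam": "TaiKadai",
    "Zhuang": "TaiKadai",
    "Dai": "TaiKadai",
    "Maonan": "TaiKadai",
    # Mon-Khmer
    "Deang": "MonKhmer",
    "Blang": "MonKhmer",
    "WaCangyuan": "MonKhmer",
    "WaXimeng": "MonKhmer",
    # Altaic: Mongolian family
    "Dongxiang": "Mongolian",
    "Mongolian": "Mongolian",
    "Tu": "Mongolian",
    # Altaic: Turkic family
    "Uyghur": "Turkic",
    "Kirgiz": "Turkic",
    "Salar": "Turkic",
    # Iranian
    "Tajik": "Iranian",
}

_LINEAGE: dict[str, tuple[str, ...]] = {
    "Chinese": ("SinoTibetan", "Chinese"),
    "TibetoBurman": ("SinoTibetan", "TibetoBurman"),
    "TaiKadai": ("TaiKadai",),
    "MonKhmer": ("MonKhmer",),
    "Mongolian": ("Altaic", "Mongolian"),
    "Turkic": ("Altaic", "Turkic"),
    "Iranian": ("Iranian",),
}

# name: (latitude N, longitude E, sample size) — coordinates are
# approximate representative locations (synthetic stand-ins), not the
# survey's sampling points.
_PANEL: dict[str, tuple[float, float, int]] = {
    "HanGansu": (36.06, 103.83, 50),
    "HanShandong": (36.65, 117.12, 53),
    "HanGuangdong": (23.13, 113.26, 54),
    "Drung": (27.74, 98.67, 40),
    "Nu": (26.90, 98.87, 42),
    "Lisu": (25.98, 98.86, 50),
    "Tibetan": (29.65, 91.10, 50),
    "Yi": (25.03, 101.55, 55),
    "Bai": (25.61, 100.27, 56),
    "Pumi": (26.45, 99.42, 45),
    "Aini": (21.96, 100.45, 50),
    "Jinuo": (22.01, 100.80, 46),
    "Lahu": (22.56, 99.93, 50),
    "Naxi": (26.86, 100.23, 50),
    "Li": (18.78, 109.52, 48),
    "Mulam": (24.78, 108.90, 50),
    "Zhuang": (22.82, 108.32, 95),
    "Dai": (21.90, 100.97, 58),
    "Maonan": (24.83, 108.25, 50),
    "Deang": (24.43, 98.59, 47),
    "Blang": (21.70, 100.40, 44),
    "WaCangyuan": (23.15, 99.25, 50),
    "WaXimeng": (22.77, 99.59, 50),
    "Dongxiang": (35.66, 103.39, 50),
    "Mongolian": (40.84, 111.75, 50),
    "Tu": (36.84, 101.96, 37),
    "Uyghur": (43.83, 87.62, 66),
    "Kirgiz": (39.72, 76.17, 52),
    "Salar": (35.85, 102.49, 50),
    "Tajik": (37.77, 75.23, 50),
}

STUDY_POPULATIONS: list[PopulationMeta] = [
    PopulationMeta(
        name=name,
        latitude=lat,
        longitude=lon,
        lineage=_LINEAGE[LANGUAGE_GROUP[name]] + (name,),
        sample_size=n,
    )
    for name, (lat, lon, n) in _PANEL.items()
]

#: Dated language tree: internal nodes carry ages in years before
#: present.  Only three ages are fixed by the design — the split of
#: Chinese from Tibeto-Burman at 7,000 yrs BP, of Mongolian from Turkic
#: at 8,000 yrs BP, and the root joining everything else at 50,000 yrs
#: BP; all finer structure is collapsed into these nodes.
DEFAULT_LANGUAGE_TREE: dict = {
    "name": "root",
    "age": 50000.0,
    "children": [
        {
            "name": "SinoTibetan",
            "age": 7000.0,
            "children": [{"name": "Chinese"}, {"name": "TibetoBurman"}],
        },
        {
            "name": "Altaic",
            "age": 8000.0,
            "children": [{"name": "Mongolian"}, {"name": "Turkic"}],
        },
        {"name": "TaiKadai"},
        {"name": "MonKhmer"},
        {"name": "Iranian"},
    ],
}

#: High-missingness design cells emulating the survey's failure pattern:
#: five (population, locus) cells above 60% missing, spread over four
#: populations and two loci, so the 40%-tolerance policy drops exactly
#: those four populations from the full-loci subset and those two loci
#: from the full-population subset.
STUDY_MISSINGNESS_CELLS: dict[tuple[str, str], float] = {
    ("Jinuo", "D3S1304"): 0.65,
    ("Tibetan", "D3S1304"): 0.62,
    ("WaXimeng", "D3S1304"): 0.63,
    ("WaCangyuan", "D3S1580"): 0.66,
    ("WaXimeng", "D3S1580"): 0.68,
}
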