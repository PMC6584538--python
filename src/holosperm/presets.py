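"""Reference designs and breed population statistics.

The default phantom reproduces published morphometry of bovine spermatozoa:
2D silhouette lengths (head length/width, midpiece and tail length) for
Holstein (HO) dairy and Korean native (KN) beef cattle, and compartment RI
values placed inside the three intracellular RI bands used for substance
decomposition (RI-I low-density surface material, RI-II "skeletal"
material, RI-III dense mitochondria-associated material confined to the
midpiece core).

Radii and head thickness are not published for these breeds; the defaults
(midpiece radius 0.4 µm with a 0.25 µm core, tail tapering 0.35 → 0.1 µm,
head thickness = width/2) are anatomically plausible stand-ins and remain
configurable everywhere.
"""

from __future__ import annotations

from dataclasses import replace

from .phantoms import BreedPopulationSpec, SpermDesign

__all__ = [
    "HO_2D_STATS",
    "KN_2D_STATS",
    "default_design",
    "ho_design",
    "kn_design",
    "default_population_spec",
    "MEDIUM_RI",
    "RI_INCREMENT_ML_PER_G",
]

#: RI of phosphate-buffered saline, the immersion medium.
MEDIUM_RI = 1.337

#: Specific refraction increment of cytoplasmic biomolecules (mL/g).
RI_INCREMENT_ML_PER_G = 0.19

# Published 2D morphometry, mean ± SD in µm, n = 30 cells/breed.
HO_2D_STATS = {
    "head_length": (9.053, 0.310),
    "head_width": (4.954, 0.268),
    "midpiece_length": (13.926, 0.547),
    "tail_length": (46.415, 1.386),
}
KN_2D_STATS = {
    "head_length": (9.229, 0.297),
    "head_width": (5.241, 0.297),
    "midpiece_length": (13.245, 0.299),
    "tail_length": (47.750, 1.373),
}


def default_design() -> SpermDesign:
    """Holstein-mean bovine design: the package-wide default phantom."""
    return ho_design()


def ho_design() -> SpermDesign:
    hl, hw = HO_2D_STATS["head_length"][0], HO_2D_STATS["head_width"][0]
    return SpermDesign(
        head_length=hl,
        head_width=hw,
        head_thickness=hw / 2.0,
        midpiece_length=HO_2D_STATS["midpiece_length"][0],
        midpiece_radius=0.4,
        tail_length=HO_2D_STATS["tail_length"][0],
        tail_base_radius=0.35,
        tail_tip_radius=0.1,
        head_ri=1.3514,          # implies ≈76 fg/µm³ at the default increment
        midpiece_ri=1.3629,      # upper RI-II
        midpiece_core_ri=1.3731,  # RI-III mid-band
        tail_ri=1.3580,          # RI-II: the tail carries no RI-III material
        curvature=0.0,
    )


def kn_design() -> SpermDesign:
    hl, hw = KN_2D_STATS["head_length"][0], KN_2D_STATS["head_width"][0]
    return replace(
        ho_design(),
        head_length=hl,
        head_width=hw,
        head_thickness=hw / 2.0,
        midpiece_length=KN_2D_STATS["midpiece_length"][0],
        tail_length=KN_2D_STATS["tail_length"][0],
    )


def default_population_spec(n_per_group: int = 30, seed: int = 0) -> BreedPopulationSpec:
    """Two-breed spec matching the published 2D means ± SDs (30 cells/breed:
    five bulls × six spermatozoa each, modelled as one flat sample)."""
    groups = {}
    for label, stats2d in (("HO", HO_2D_STATS), ("KN", KN_2D_STATS)):
        params = dict(stats2d)
        hw_mean, hw_sd = stats2d["head_width"]
        params["head_thickness"] = (hw_mean / 2.0, hw_sd / 2.0)
        groups[label] = params
    return BreedPopulationSpec(
        groups=groups,
        n_per_group=n_per_group,
        seed=seed,
        base_design=default_design(),
        medium_ri=MEDIUM_RI,
    )
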