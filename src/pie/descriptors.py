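"""Per-pocket descriptor vectors: 89 base + 10 amalgamated + 10 geometric.

The base block mirrors a volume + pharmacophore-by-buriedness scheme:
pocket volume (probe count x spacing^3, A^3), one overall probe count
for each of eight categories (the seven probe types plus a total-polar
category), and those same eight counts split over ten normalized
buriedness deciles — 1 + 8 + 80 = 89 values.

The amalgamated block reduces the counts to interpretable fractions
(hydrophobicity, aromaticity, donor/acceptor/ionizable/polar/dummy
content, exposure, mean buriedness), all in [0, 1].

The geometric block characterizes the probe cloud shape through the
gyration tensor (eigenvalues l1 <= l2 <= l3) and the unit-mass inertia
tensor (principal moments I1 <= I2 <= I3):

  Rg            = sqrt(l1 + l2 + l3)
  asphericity   = ((l3-l2)^2 + (l2-l1)^2 + (l1-l3)^2) / (2 (l1+l2+l3)^2)
  spherocity    = 3 l1 / (l1 + l2 + l3)
  eccentricity  = sqrt(1 - I1/I3)
  inertial shape factor = I2 / (I1 I3)
  PMI1..3, NPR1 = I1/I3, NPR2 = I2/I3

These are rotation- and translation-invariant functions of the probe
coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cavity import CavityParams, Pocket, ProbeType

CATEGORY_ORDER = ["hydrophobic", "aromatic", "hb_acceptor", "hb_donor",
                  "acceptor_neg", "donor_pos", "dummy", "polar"]
_TYPE_TO_CATEGORY = {
    ProbeType.HYDROPHOBIC: "hydrophobic",
    ProbeType.AROMATIC: "aromatic",
    ProbeType.HB_ACCEPTOR: "hb_acceptor",
    ProbeType.HB_DONOR: "hb_donor",
    ProbeType.ACCEPTOR_NEG: "acceptor_neg",
    ProbeType.DONOR_POS: "donor_pos",
    ProbeType.DUMMY: "dummy",
}
POLAR_CATEGORIES = ("hb_acceptor", "hb_donor", "acceptor_neg", "donor_pos")

N_BASE = 89
N_AMALGAMATED = 10
N_GEOMETRIC = 10
N_DESCRIPTORS = N_BASE + N_AMALGAMATED + N_GEOMETRIC

AMALGAMATED_NAMES = [
    "frac_hydrophobic", "frac_aromatic", "frac_hb_donor", "frac_hb_acceptor",
    "frac_pos_ionizable", "frac_neg_ionizable", "frac_polar", "frac_dummy",
    "exposure", "mean_buriedness",
]
GEOMETRIC_NAMES = [
    "radius_of_gyration", "asphericity", "spherocity", "eccentricity",
    "inertial_shape_factor", "pmi1", "pmi2", "pmi3", "npr1", "npr2",
]


def base_descriptor_names() -> list[str]:
    names = ["volume"]
    names += [f"count_{cat}" for cat in CATEGORY_ORDER]
    for cat in CATEGORY_ORDER:
        names += [f"count_{cat}_bur{d}" for d in range(1, 11)]
    return names


def descriptor_names() -> list[str]:
    """The fixed, globally ordered list of all 109 descriptor names."""
    return base_descriptor_names() + AMALGAMATED_NAMES + GEOMETRIC_NAMES


@dataclass
class DescriptorVector:
    pocket_id: str
    names: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.names) != N_DESCRIPTORS or len(self.values) != N_DESCRIPTORS:
            raise ValueError(f"descriptor vector must have length "
                             f"{N_DESCRIPTORS}")

    def as_series(self) -> pd.Series:
        return pd.Series(self.values, index=self.names, name=self.pocket_id)


def _decile(bnorm: float) -> int:
    """Right-closed decile index 1..10 of a normalized buriedness in [0,1]."""
    if bnorm <= 0.1:
        return 1
    return int(min(10, np.ceil(bnorm * 10 - 1e-12)))


def base_descriptors(pocket: Pocket, spacing: float = 1.5,
                     n_rays: int = 120) -> np.ndarray:
    """Volume plus per-category totals and buriedness-decile counts (89)."""
    vals = np.zeros(N_BASE)
    vals[0] = pocket.n_probes * spacing ** 3
    counts = {cat: 0 for cat in CATEGORY_ORDER}
    bins = {cat: np.zeros(10) for cat in CATEGORY_ORDER}
    for probe in pocket.probes:
        cat = _TYPE_TO_CATEGORY[probe.probe_type]
        d = _decile(probe.buriedness / n_rays)
        cats = [cat] + (["polar"] if cat in POLAR_CATEGORIES else [])
        for c in cats:
            counts[c] += 1
            bins[c][d - 1] += 1
    for i, cat in enumerate(CATEGORY_ORDER):
        vals[1 + i] = counts[cat]
    off = 1 + len(CATEGORY_ORDER)
    for i, cat in enumerate(CATEGORY_ORDER):
        vals[off + 10 * i: off + 10 * (i + 1)] = bins[cat]
    return vals


def amalgamated_descriptors(base: np.ndarray,
                            n_rays: int = 120,
                            pocket: Optional[Pocket] = None) -> np.ndarray:
    """Fractions of total probes plus exposure and mean buriedness (10).

    Exposure is the fraction of probes in the lowest three buriedness
    deciles; mean buriedness is averaged on the [0, 1] normalized scale.
    Both need the per-probe buriedness, hence the pocket argument.
    """
    base = np.asarray(base, dtype=float)
    idx = {cat: 1 + i for i, cat in enumerate(CATEGORY_ORDER)}
    total = sum(base[idx[c]] for c in CATEGORY_ORDER if c != "polar")
    if total <= 0:
        raise ValueError("pocket has zero probes")
    fr = lambda cat: base[idx[cat]] / total
    if pocket is not None:
        bnorm = np.array([p.buriedness / n_rays for p in pocket.probes])
        exposure = float(np.mean(bnorm <= 0.3))
        mean_bur = float(np.mean(bnorm))
    else:
        # recover from the decile counts of the all-category histogram
        off = 1 + len(CATEGORY_ORDER)
        hist = np.zeros(10)
        for i, cat in enumerate(CATEGORY_ORDER):
            if cat == "polar":
                continue
            hist += base[off + 10 * i: off + 10 * (i + 1)]
        exposure = float(hist[:3].sum() / total)
        centers = (np.arange(10) + 0.5) / 10.0
        mean_bur = float((hist * centers).sum() / total)
    return np.array([
        fr("hydrophobic"), fr("aromatic"), fr("hb_donor"), fr("hb_acceptor"),
        fr("donor_pos"), fr("acceptor_neg"), fr("polar"), fr("dummy"),
        exposure, mean_bur,
    ])


def gyration_spectrum(xyz: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues of the gyration tensor and unit-mass inertia tensor,
    each sorted ascending."""
    xyz = np.asarray(xyz, dtype=float)
    centered = xyz - xyz.mean(axis=0)
    n = len(xyz)
    gyr = centered.T @ centered / n
    lam = np.sort(np.linalg.eigvalsh(gyr))
    r2 = np.einsum("ij,ij->i", centered, centered)
    inertia = np.eye(3) * r2.sum() - centered.T @ centered
    moments = np.sort(np.linalg.eigvalsh(inertia))
    return np.clip(lam, 0.0, None), np.clip(moments, 0.0, None)


def geometric_descriptors(pocket: Pocket) -> np.ndarray:
    """Shape descriptors of the probe cloud (10 values).

    Degenerate clouds use fixed conventions: a single probe has Rg 0,
    asphericity 0, spherocity 1, eccentricity 0, NPR1 = NPR2 = 1 and
    inertial shape factor 0; a perfectly collinear cloud (I1 = 0) has
    eccentricity 1 and inertial shape factor 0.
    """
    xyz = pocket.probe_coords()
    if len(xyz) == 0:
        raise ValueError("pocket has zero probes")
    lam, I = gyration_spectrum(xyz)
    trace = float(lam.sum())
    rg = float(np.sqrt(trace))
    if trace <= 1e-12:   # single point (or coincident probes)
        return np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0, 1.0])
    asph = float(((lam[2] - lam[1]) ** 2 + (lam[1] - lam[0]) ** 2 +
                  (lam[0] - lam[2]) ** 2) / (2.0 * trace ** 2))
    spher = float(3.0 * lam[0] / trace)
    i1, i2, i3 = (float(v) for v in I)
    ecc = float(np.sqrt(max(0.0, 1.0 - i1 / i3))) if i3 > 0 else 0.0
    isf = float(i2 / (i1 * i3)) if i1 > 0 and i3 > 0 else 0.0
    npr1 = i1 / i3 if i3 > 0 else 1.0
    npr2 = i2 / i3 if i3 > 0 else 1.0
    return np.array([rg, asph, spher, ecc, isf, i1, i2, i3, npr1, npr2])


def assemble_descriptor_vector(pocket: Pocket,
                               params: CavityParams | None = None,
                               ) -> DescriptorVector:
    """Concatenate base (89) || amalgamated (10) || geometric (10)."""
    if params is None:
        params = CavityParams()
    base = base_descriptors(pocket, spacing=params.spacing,
                            n_rays=params.n_rays)
    amalg = amalgamated_descriptors(base, n_rays=params.n_rays, pocket=pocket)
    geo = geometric_descriptors(pocket)
    return DescriptorVector(pocket_id=pocket.pocket_id,
                            names=descriptor_names(),
                            values=np.concatenate([base, amalg, geo]))


def descriptor_table(pockets: Sequence[Pocket],
                     params: CavityParams | None = None,
                     classes: Optional[dict[str, str]] = None) -> pd.DataFrame:
    """One row per pocket: 109 descriptors plus metadata columns."""
    rows = []
    for pocket in pockets:
        vec = assemble_descriptor_vector(pocket, params=params)
        row = vec.as_series()
        row["structure_id"] = pocket.structure_id
        row["source"] = pocket.source.value
        row["pocket_class"] = (classes or {}).get(pocket.pocket_id,
                                                  pocket.source.value)
        rows.append(row)
    df = pd.DataFrame(rows)
    df.index.name = "pocket_id"
    return df
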