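"""Synthetic Circle of Willis anatomies from cohort morphometry.

No patient imaging ships with the package; instead, reference-topology
networks are generated with per-vessel axial lengths and mean radii drawn
from the cohort morphometry table (mean and SD per vessel and scan,
truncated at two standard deviations).  Centerlines are synthesized as
straight 3-D lines sampled at ~1 point/mm with a mild symmetric linear
taper — geometric realism beyond (arc length, radius profile) is
irrelevant to a 1-D model.  Optional features: missing communicating
arteries (the degenerate junctions become serial connections), smooth
axisymmetric aneurysmal enlargements, and paired initial/follow-up scans
differing by vessel-wise lognormal perturbations, aneurysm growth, and a
global area distortion emulating an imaging-resolution change.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .centerline import Centerline
from .errors import ConfigurationError, InvalidInputError
from .longitudinal import ScanPair
from .network import VascularNetwork, assemble_network
from .reduction import reduce_centerline

__all__ = [
    "MorphometryTable",
    "Aneurysm",
    "SyntheticPatientSpec",
    "CANONICAL_CONNECTIVITY",
    "generate_network",
    "assemble_from_centerlines",
    "insert_aneurysm",
    "synth_pair_centerlines",
    "make_scan_pair",
    "default_patient",
]

#: Canonical wiring of the 30-artery reference network.  Each artery maps to
#: (proximal node, distal node); nodes are named, never indexed.
CANONICAL_CONNECTIVITY: dict[str, tuple[str, str]] = {}
for _s in ("R", "L"):
    CANONICAL_CONNECTIVITY.update({
        f"{_s} ICA G1": (f"in {_s} ICA", f"j {_s} ICA-OA"),
        f"{_s} OA": (f"j {_s} ICA-OA", f"out {_s} OA"),
        f"{_s} ICA G2": (f"j {_s} ICA-OA", f"j {_s} ICA-PCoA"),
        f"{_s} ICA G3": (f"j {_s} ICA-PCoA", f"j {_s} ICA term"),
        f"{_s} PCoA": (f"j {_s} ICA-PCoA", f"j {_s} PCA-PCoA"),
        f"{_s} MCA G1": (f"j {_s} ICA term", f"j {_s} MCA 1-2"),
        f"{_s} MCA G2": (f"j {_s} MCA 1-2", f"j {_s} MCA 2-3"),
        f"{_s} MCA G3": (f"j {_s} MCA 2-3", f"out {_s} MCA"),
        f"{_s} ACA G1": (f"j {_s} ICA term", f"j {_s} ACA"),
        f"{_s} ACA G2": (f"j {_s} ACA", f"j {_s} ACA 2-3"),
        f"{_s} ACA G3": (f"j {_s} ACA 2-3", f"out {_s} ACA"),
        f"{_s} PCA G1": ("j BA head", f"j {_s} PCA-PCoA"),
        f"{_s} PCA G2": (f"j {_s} PCA-PCoA", f"j {_s} PCA 2-3"),
        f"{_s} PCA G3": (f"j {_s} PCA 2-3", f"out {_s} PCA"),
    })
CANONICAL_CONNECTIVITY["BA"] = ("in BA", "j BA head")
CANONICAL_CONNECTIVITY["ACoA"] = ("j R ACA", "j L ACA")

CANONICAL_LABELS = list(CANONICAL_CONNECTIVITY)


class MorphometryTable:
    """Per-vessel mean +- SD of axial length and radius, for both scans."""

    def __init__(self, df: pd.DataFrame):
        required = {
            "label",
            "length_sc1_mean_cm", "length_sc1_sd_cm", "radius_sc1_mean_cm", "radius_sc1_sd_cm",
            "length_sc2_mean_cm", "length_sc2_sd_cm", "radius_sc2_mean_cm", "radius_sc2_sd_cm",
        }
        missing = required - set(df.columns)
        if missing:
            raise InvalidInputError(f"morphometry table missing columns {sorted(missing)}")
        if (df[[c for c in df.columns if c.endswith("mean_cm")]] <= 0).any().any():
            raise InvalidInputError("morphometry means must be > 0")
        if (df[[c for c in df.columns if c.endswith("sd_cm")]] < 0).any().any():
            raise InvalidInputError("morphometry SDs must be >= 0")
        self._df = df.set_index("label")

    @classmethod
    def cohort(cls) -> "MorphometryTable":
        """The packaged 7-patient cohort morphometry."""
        ref = resources.files("cowflow.data").joinpath("cohort_morphometry.csv")
        with resources.as_file(ref) as p:
            return cls(pd.read_csv(p))

    @classmethod
    def from_csv(cls, path: str | Path) -> "MorphometryTable":
        return cls(pd.read_csv(path))

    @property
    def labels(self) -> list[str]:
        return list(self._df.index)

    def stats(self, label: str, scan: str = "sc1") -> tuple[float, float, float, float]:
        """(length mean, length SD, radius mean, radius SD), in cm."""
        if scan not in ("sc1", "sc2"):
            raise InvalidInputError(f"scan must be 'sc1' or 'sc2', got {scan!r}")
        r = self._df.loc[label]
        return (
            float(r[f"length_{scan}_mean_cm"]), float(r[f"length_{scan}_sd_cm"]),
            float(r[f"radius_{scan}_mean_cm"]), float(r[f"radius_{scan}_sd_cm"]),
        )

    def zeroed_sd(self) -> "MorphometryTable":
        """Copy with all SDs at zero (deterministic cohort-mean anatomy)."""
        df = self._df.reset_index().copy()
        for c in df.columns:
            if c.endswith("sd_cm"):
                df[c] = 0.0
        return MorphometryTable(df)

    def symmetrized(self) -> "MorphometryTable":
        """Copy with left-side rows set to the right-side values (for
        symmetry studies)."""
        df = self._df.reset_index().copy().set_index("label")
        for lbl in df.index:
            if lbl.startswith("L "):
                df.loc[lbl] = df.loc["R " + lbl[2:]]
        return MorphometryTable(df.reset_index())


@dataclass(frozen=True)
class Aneurysm:
    """Axisymmetric enlargement of one host vessel.

    ``enlargement`` is the peak relative radius increase (0.5 -> 1.5x at
    the apex), ``extent`` the axial window as a fraction of vessel length,
    ``growth`` the additional enlargement in the follow-up scan."""

    vessel: str
    enlargement: float = 0.5
    extent: float = 0.5
    growth: float = 0.0

    def __post_init__(self):
        if self.enlargement < 0:
            raise InvalidInputError("enlargement must be >= 0")
        if not 0.0 < self.extent <= 1.0:
            raise InvalidInputError("extent fraction must be in (0, 1]")


@dataclass(frozen=True)
class SyntheticPatientSpec:
    """Controls for one synthetic patient (and its scan pair)."""

    seed: int = 0
    has_ACoA: bool = True
    has_R_PCoA: bool = True
    has_L_PCoA: bool = True
    aneurysms: tuple[Aneurysm, ...] = ()
    radius_perturbation: float = 0.10   # lognormal sigma on scan-2 radii
    length_perturbation: float = 0.05   # lognormal sigma on scan-2 lengths
    resolution_distortion: float = 1.0  # global area factor k on scan 2
    taper: float = 0.05                 # symmetric linear taper fraction
    waviness: float = 0.0               # radius modulation amplitude
    gamma: float = 0.01                 # reduction smoothness threshold

    def __post_init__(self):
        if self.resolution_distortion <= 0:
            raise InvalidInputError("resolution distortion k must be > 0")
        if not 0 <= self.taper < 1:
            raise InvalidInputError("taper fraction must be in [0, 1)")

    def active_labels(self) -> list[str]:
        drop = set()
        if not self.has_ACoA:
            drop.add("ACoA")
        if not self.has_R_PCoA:
            drop.add("R PCoA")
        if not self.has_L_PCoA:
            drop.add("L PCoA")
        return [l for l in CANONICAL_LABELS if l not in drop]


def default_patient(seed: int = 0, **overrides) -> SyntheticPatientSpec:
    """A cohort-typical patient: one growing aneurysm on the left posterior
    communicating artery."""
    kw = dict(seed=seed, aneurysms=(Aneurysm("L PCoA", 0.5, 0.5, growth=0.3),))
    kw.update(overrides)
    return SyntheticPatientSpec(**kw)


# golden-angle directions keep synthesized centerlines deterministic and
# non-degenerate without pretending anatomical realism
def _direction(i: int) -> np.ndarray:
    ang = 2.399963229728653 * (i + 1)
    z = ((i * 37) % 17 - 8) / 17.0
    r = np.sqrt(max(1e-6, 1.0 - z * z))
    return np.array([r * np.cos(ang), r * np.sin(ang), z])


def _synth_centerline(
    label: str, length: float, radius: float, spec: SyntheticPatientSpec,
    aneurysm: Aneurysm | None = None, extra_enlargement: float = 0.0,
    rng: np.random.Generator | None = None,
) -> Centerline:
    n = max(2, int(round(length * 10)) + 1)
    s = np.linspace(0.0, length, n)
    # symmetric linear taper keeps the length-weighted mean radius exact
    r = radius * (1.0 + spec.taper * (1.0 - 2.0 * s / length))
    if spec.waviness > 0:
        k = max(1, int(round(length / 0.8)))
        phase = 0.0 if rng is None else rng.uniform(0, 2 * np.pi)
        r = r * (1.0 + spec.waviness * np.sin(2 * np.pi * k * s / length + phase))
    if aneurysm is not None:
        e = aneurysm.enlargement + extra_enlargement
        w = aneurysm.extent * length
        s0 = 0.5 * (length - w)
        inside = (s >= s0) & (s <= s0 + w)
        bump = np.zeros_like(s)
        bump[inside] = np.sin(np.pi * (s[inside] - s0) / w) ** 2
        r = r * (1.0 + e * bump)
    i = CANONICAL_LABELS.index(label) if label in CANONICAL_LABELS else hashabs(label)
    origin = _direction(i + 7) * 3.0
    xyz = origin[None, :] + s[:, None] * _direction(i)[None, :]
    return Centerline.from_arrays(label, xyz, r)


def hashabs(label: str) -> int:
    return sum(ord(c) for c in label) % 97


def _sample_geometry(
    spec: SyntheticPatientSpec, morph: MorphometryTable, rng: np.random.Generator,
    scan: str = "sc1",
) -> dict[str, tuple[float, float]]:
    """Per-vessel (length, radius) from truncated normals, in canonical order."""
    geom = {}
    for lbl in spec.active_labels():
        lm, lsd, rm, rsd = morph.stats(lbl, scan)
        length = float(np.clip(rng.normal(lm, lsd) if lsd > 0 else lm,
                               max(lm - 2 * lsd, 1e-3), lm + 2 * lsd))
        radius = float(np.clip(rng.normal(rm, rsd) if rsd > 0 else rm,
                               max(rm - 2 * rsd, 1e-3), rm + 2 * rsd))
        geom[lbl] = (length, radius)
    return geom


def _centerlines(spec: SyntheticPatientSpec, geom: dict[str, tuple[float, float]],
                 rng: np.random.Generator, grown: bool = False) -> dict[str, Centerline]:
    an_by_vessel = {a.vessel: a for a in spec.aneurysms}
    unknown = set(an_by_vessel) - set(geom)
    if unknown:
        raise ConfigurationError(f"aneurysm host vessels not in network: {sorted(unknown)}")
    cls_: dict[str, Centerline] = {}
    for lbl, (length, radius) in geom.items():
        an = an_by_vessel.get(lbl)
        cls_[lbl] = _synth_centerline(lbl, length, radius, spec, aneurysm=an,
                                      extra_enlargement=(an.growth if an and grown else 0.0),
                                      rng=rng)
    return cls_


def assemble_from_centerlines(centerlines: dict[str, Centerline],
                              gamma: float = 0.01) -> VascularNetwork:
    """Reduce canonical-labelled centerlines and wire them up."""
    arteries = [reduce_centerline(cl, gamma) for cl in centerlines.values()]
    conn = {lbl: CANONICAL_CONNECTIVITY[lbl] for lbl in centerlines}
    return assemble_network(arteries, conn)


def _build(spec: SyntheticPatientSpec, geom: dict[str, tuple[float, float]],
           rng: np.random.Generator, grown: bool = False) -> VascularNetwork:
    return assemble_from_centerlines(_centerlines(spec, geom, rng, grown), spec.gamma)


def generate_network(
    spec: SyntheticPatientSpec, morph: MorphometryTable | None = None,
    scan: str = "sc1",
) -> VascularNetwork:
    """Generate one reference-topology network.

    Deterministic for a fixed spec (seed included).  With all SDs zero the
    vessel summaries reproduce the cohort means exactly."""
    morph = morph or MorphometryTable.cohort()
    rng = np.random.default_rng(spec.seed)
    geom = _sample_geometry(spec, morph, rng, scan)
    return _build(spec, geom, rng)


def insert_aneurysm(
    net: VascularNetwork, vessel: str, enlargement: float, extent: float,
    gamma: float = 0.01,
) -> VascularNetwork:
    """Superpose a smooth axisymmetric bump on one vessel's radius profile.

    The host profile is resampled at ~1 point/mm, multiplied by
    ``1 + enlargement * sin^2`` over the central ``extent`` fraction, and
    re-reduced so the result remains a valid monotonic-segment chain."""
    if vessel not in net.arteries:
        raise InvalidInputError(f"unknown vessel {vessel!r}")
    an = Aneurysm(vessel, enlargement, extent)
    art = net.arteries[vessel]
    L = art.length
    s = np.linspace(art.segments[0].s0, art.segments[0].s0 + L,
                    max(2, int(round(L * 10)) + 1))
    r = art.radius_at(s)
    if enlargement > 0:
        w = an.extent * L
        s0 = s[0] + 0.5 * (L - w)
        inside = (s >= s0) & (s <= s0 + w)
        bump = np.zeros_like(s)
        bump[inside] = np.sin(np.pi * (s[inside] - s0) / w) ** 2
        r = r * (1.0 + enlargement * bump)
    i = CANONICAL_LABELS.index(vessel) if vessel in CANONICAL_LABELS else hashabs(vessel)
    xyz = s[:, None] * _direction(i)[None, :]
    new_art = reduce_centerline(Centerline.from_arrays(vessel, xyz, r), gamma)
    return net.with_arteries({vessel: new_art})


def synth_pair_centerlines(
    spec: SyntheticPatientSpec, morph: MorphometryTable | None = None,
) -> tuple[dict[str, Centerline], dict[str, Centerline], dict]:
    """Raw centerline dialect of a scan pair, before any mesh reduction.

    Scan 2 = scan 1 with per-vessel lognormal radius/length perturbations,
    aneurysm growth applied, then all radii multiplied by sqrt(k) so every
    reference area carries the resolution distortion ``k``.  The truth
    record holds ``k`` and the per-vessel perturbation factors."""
    morph = morph or MorphometryTable.cohort()
    rng = np.random.default_rng(spec.seed)
    geom1 = _sample_geometry(spec, morph, rng, "sc1")
    cls1 = _centerlines(spec, geom1, rng)

    k = spec.resolution_distortion
    radius_f, length_f = {}, {}
    geom2 = {}
    for lbl, (length, radius) in geom1.items():
        rf = float(rng.lognormal(0.0, spec.radius_perturbation)) if spec.radius_perturbation else 1.0
        lf = float(rng.lognormal(0.0, spec.length_perturbation)) if spec.length_perturbation else 1.0
        radius_f[lbl] = rf
        length_f[lbl] = lf
        geom2[lbl] = (length * lf, radius * rf * float(np.sqrt(k)))
    cls2 = _centerlines(spec, geom2, rng, grown=True)
    truth = {"k": k, "radius_factors": radius_f, "length_factors": length_f,
             "seed": spec.seed}
    return cls1, cls2, truth


def make_scan_pair(
    spec: SyntheticPatientSpec, morph: MorphometryTable | None = None,
) -> tuple[ScanPair, dict]:
    """Paired initial/follow-up networks plus the generation truth record.

    The returned pair is alpha-calibrated; with no perturbations the
    recovered alpha equals 1/k exactly (pure algebra on the inlet areas)."""
    cls1, cls2, truth = synth_pair_centerlines(spec, morph)
    net1 = assemble_from_centerlines(cls1, spec.gamma)
    net2 = assemble_from_centerlines(cls2, spec.gamma)
    pair = ScanPair.calibrated(net1, net2)
    return pair, truth
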