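"""Seeded synthetic study generator.

Emulates the statistical structure of a ~167-patient hepatectomy cohort with
38.9% early recurrence (ER): per-patient three-phase (NC/ART/PV) tumor-ROI
slice stacks with class-dependent contrast patterns, plus a clinical record
whose class-conditional category frequencies default to the reference
contingency-table proportions (e.g. P(size >= 5 cm | ER) = 37/65).

The images make no attempt at radiological realism — no organ anatomy, no CT
physics.  Each slice is a smooth background field with an elliptical lesion;
the class signal is planted the way aggressive tumors present on contrast CT:
stronger arterial-phase rim enhancement, deeper portal-venous washout,
boundary irregularity and heavier internal speckle for ER lesions.  The
central slice of the stack has the largest lesion cross-section.

Everything is deterministic given ``CohortSpec.seed``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image
from scipy.ndimage import gaussian_filter

from . import clinical as cl
from .backbone import PHASES

__all__ = [
    "PhaseEffects",
    "CohortSpec",
    "SyntheticPatient",
    "Cohort",
    "table1_frequencies",
    "draw_labels",
    "generate_clinical_record",
    "generate_phase_images",
    "generate_cohort",
    "export_cohort",
    "load_cohort",
]


@dataclass(frozen=True)
class PhaseEffects:
    """Class-conditional lesion phenotype distributions (image units in [0, 1]).

    NC: lesions are mildly hypodense in both classes.  ART: rim enhancement,
    on average stronger for ER.  PV: washout (lesion darker than background),
    on average deeper for ER.  ``speckle`` is the within-lesion multiplicative
    noise sd; ``roughness`` the angular boundary perturbation amplitude.

    Each patient draws their own rim amplitude, washout depth, speckle and
    roughness from normal distributions around the class means (``*_sd``),
    so the classes overlap: the imaging signal is informative but imperfect,
    the regime in which adding clinical data helps.  The class separations
    are roughly one within-class standard deviation per feature.
    """

    nc_offset: float = -0.05
    art_core: float = 0.06
    art_rim_ner: float = 0.10
    art_rim_er: float = 0.16
    art_rim_sd: float = 0.05
    pv_washout_ner: float = 0.05
    pv_washout_er: float = 0.10
    pv_washout_sd: float = 0.03
    speckle_ner: float = 0.030
    speckle_er: float = 0.055
    speckle_sd: float = 0.015
    roughness_ner: float = 0.05
    roughness_er: float = 0.13
    roughness_sd: float = 0.04


def table1_frequencies() -> dict[str, dict[int, np.ndarray]]:
    """Class-conditional category probabilities from the reference counts.

    Returns {variable: {label: probs over ordered categories}} with label
    0 = NER, 1 = ER; category order matches the variable definitions.
    """
    out: dict[str, dict[int, np.ndarray]] = {}
    for name, rows in cl.TABLE1_COUNTS.items():
        arr = np.asarray(rows, dtype=float)
        if name in cl._REVERSED_ROWS:
            arr = arr[::-1]
        out[name] = {
            0: arr[:, 0] / arr[:, 0].sum(),
            1: arr[:, 1] / arr[:, 1].sum(),
        }
    return out


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 167
    er_prevalence: float = 0.389
    slices_min: int = 3
    slices_max: int = 7
    image_size: tuple[int, int] = (64, 64)
    phase_effects: PhaseEffects = field(default_factory=PhaseEffects)
    clinical_freqs: dict | None = None  # defaults to table1_frequencies()
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.er_prevalence < 1.0:
            raise ValueError("er_prevalence must be in (0, 1)")
        if self.n_patients < 2:
            raise ValueError("need at least 2 patients")
        if self.slices_min < 1 or self.slices_max < self.slices_min:
            raise ValueError("invalid slice range")

    def freqs(self) -> dict:
        return self.clinical_freqs or table1_frequencies()


@dataclass
class SyntheticPatient:
    patient_id: str
    label: int
    images: np.ndarray            # (S, 3, H, W) float32 in [0,1], phases NC/ART/PV
    areas: list[float]            # per-slice lesion area (pixels)
    record: cl.ClinicalRecord
    clinical_vector: np.ndarray   # (9,) int


@dataclass
class Cohort:
    patients: list[SyntheticPatient]
    spec: CohortSpec | None = None

    def __len__(self):
        return len(self.patients)

    def labels(self) -> dict[str, int]:
        return {p.patient_id: p.label for p in self.patients}


# -- sampling pieces -------------------------------------------------------

def draw_labels(n: int, prevalence: float, rng: np.random.Generator) -> np.ndarray:
    """Independent Bernoulli(prevalence) ER labels."""
    return (rng.random(n) < prevalence).astype(int)


# raw-value ranges used to back continuous values out of a sampled category
_RAW_RANGES = {
    "age": ((35.0, 59.9), (60.0, 82.0)),
    "tumor_size_mm": ((12.0, 49.5), (50.0, 130.0)),
    "tumor_number": ((1.0, 1.0), (2.0, 4.0)),
    "nlr": ((0.8, 2.79), (2.8, 8.0)),
    "alt": ((8.0, 39.5), (40.0, 210.0)),
    "ast": ((12.0, 49.5), (50.0, 180.0)),
    "akp": ((40.0, 124.5), (125.0, 300.0)),
    "ggt": ((10.0, 44.5), (45.0, 400.0)),
    "alb": ((30.0, 39.5), (40.0, 54.0)),
    "tb": ((5.0, 20.4), (20.5, 55.0)),
    "afp": ((1.0, 8.9), (9.0, 1200.0)),
}


def generate_clinical_record(
    patient_id: str, label: int, freqs: dict, rng: np.random.Generator
) -> cl.ClinicalRecord:
    """Sample raw clinical values whose dichotomization follows the
    class-conditional category frequencies (variables independent given class)."""
    raw: dict[str, object] = {}
    for d in cl.CLINICAL_VARIABLES:
        p = freqs[d.name][label]
        cat = int(rng.choice(len(p), p=p))
        if d.kind == "categorical":
            raw[d.name] = d.categories[cat]
        else:
            lo, hi = _RAW_RANGES[d.name][cat]
            if d.name == "tumor_number":
                raw[d.name] = 1 if cat == 0 else int(rng.integers(2, 5))
            else:
                raw[d.name] = round(float(rng.uniform(lo, hi)), 2)
    return cl.dichotomize_record(cl.ClinicalRecord(patient_id, raw, label))


def _lesion_mask(h: int, w: int, cx: float, cy: float, a: float, b: float,
                 theta: float, rough: float, rng: np.random.Generator) -> np.ndarray:
    """Elliptical mask with angular radius perturbation (boundary irregularity).

    Returns a float mask in [0, 1] with value 1 inside, plus the normalized
    elliptical radius field used for rim construction.
    """
    yy, xx = np.mgrid[0:h, 0:w]
    dx, dy = xx - cx, yy - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    r = np.sqrt(u * u + v * v)
    if rough > 0:
        ang = np.arctan2(v, u)
        pert = np.zeros_like(r)
        for k in range(2, 6):
            pert += rng.normal(0, 1) * np.sin(k * ang + rng.uniform(0, 2 * np.pi))
        r = r * (1.0 + rough * pert / 4.0)
    return r


def generate_phase_images(
    label: int, spec: CohortSpec, rng: np.random.Generator
) -> tuple[np.ndarray, list[float]]:
    """One patient's (S, 3, H, W) three-phase slice stack and per-slice lesion areas."""
    h, w = spec.image_size
    fx = spec.phase_effects
    n_slices = int(rng.integers(spec.slices_min, spec.slices_max + 1))
    scale = min(h, w) / 64.0
    a0 = max(rng.uniform(9, 16) * scale, 4.5)  # at least a few pixels of lesion
    b0 = a0 * rng.uniform(0.65, 1.0)
    if min(h, w) < 2 * max(a0, b0) + 6:
        raise ValueError(
            f"image {h}x{w} smaller than lesion axes ({a0:.1f},{b0:.1f}); "
            "use at least 32x32"
        )
    cx = w / 2 + rng.uniform(-3, 3) * scale
    cy = h / 2 + rng.uniform(-3, 3) * scale
    theta = rng.uniform(0, np.pi)
    # per-patient phenotype: class-conditional normals, clipped at plausibility floors
    rough = max(rng.normal(fx.roughness_er if label else fx.roughness_ner,
                           fx.roughness_sd), 0.0)
    speckle = max(rng.normal(fx.speckle_er if label else fx.speckle_ner,
                             fx.speckle_sd), 0.005)
    rim_amp = max(rng.normal(fx.art_rim_er if label else fx.art_rim_ner,
                             fx.art_rim_sd), 0.0)
    washout = max(rng.normal(fx.pv_washout_er if label else fx.pv_washout_ner,
                             fx.pv_washout_sd), 0.0)

    center = (n_slices - 1) / 2.0
    half_span = max(n_slices / 2.0, 1.0)
    stacks, areas = [], []
    for s in range(n_slices):
        # unimodal through-plane profile: lesion radius peaks at the stack center
        frac = np.sqrt(max(1.0 - ((s - center) / half_span) ** 2, 0.15))
        r = _lesion_mask(h, w, cx, cy, a0 * frac, b0 * frac, theta, rough, rng)
        inside = (r <= 1.0).astype(np.float32)
        rim = ((r > 0.68) & (r <= 1.0)).astype(np.float32)
        core = (r <= 0.68).astype(np.float32)
        areas.append(float(inside.sum()))
        bg = 0.38 + gaussian_filter(rng.standard_normal((h, w)), 4.0) * 0.06
        noise = rng.standard_normal((h, w)) * 0.015
        spk = 1.0 + rng.standard_normal((h, w)) * speckle
        phases = []
        for phase in PHASES:
            img = bg + noise
            if phase == "NC":
                img = img + inside * fx.nc_offset
            elif phase == "ART":
                img = img + core * fx.art_core + rim * rim_amp
            else:  # PV
                img = img - inside * washout
            img = np.where(inside > 0, bg + (img - bg) * spk, img)
            phases.append(np.clip(img, 0.0, 1.0))
        stacks.append(np.stack(phases))
    images = np.stack(stacks).astype(np.float32)
    # snap to the 16-bit export grid so export/load round-trips are exact
    images = np.round(images * 65535.0) / np.float32(65535.0)
    return images.astype(np.float32), areas


def generate_cohort(spec: CohortSpec) -> Cohort:
    rng = np.random.default_rng(spec.seed)
    labels = draw_labels(spec.n_patients, spec.er_prevalence, rng)
    freqs = spec.freqs()
    patients = []
    for i, label in enumerate(labels):
        pid = f"SYN{i:04d}"
        record = generate_clinical_record(pid, int(label), freqs, rng)
        images, areas = generate_phase_images(int(label), spec, rng)
        patients.append(
            SyntheticPatient(
                pid, int(label), images, areas, record,
                cl.encode_clinical_vector(record),
            )
        )
    return Cohort(patients, spec)


# -- export / load ---------------------------------------------------------

def export_cohort(cohort: Cohort, directory) -> None:
    """Write <pid>/{NC,ART,PV}/slice_###.png (16-bit), clinical.csv, manifest.csv."""
    root = Path(directory)
    root.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    clin_rows = []
    for p in cohort.patients:
        for pi, phase in enumerate(PHASES):
            pdir = root / p.patient_id / phase
            pdir.mkdir(parents=True, exist_ok=True)
            for s in range(p.images.shape[0]):
                arr = np.round(p.images[s, pi] * 65535.0).astype(np.uint16)
                Image.fromarray(arr).save(pdir / f"slice_{s:03d}.png")
        for s, area in enumerate(p.areas):
            manifest_rows.append(
                {"patient_id": p.patient_id, "slice": s, "tumor_area": area}
            )
        row = {"patient_id": p.patient_id,
               "label": "ER" if p.label else "NER"}
        row.update({k: p.record.raw[k] for k in (d.name for d in cl.CLINICAL_VARIABLES)})
        clin_rows.append(row)
    pd.DataFrame(clin_rows, columns=cl.CSV_COLUMNS).to_csv(
        root / "clinical.csv", index=False
    )
    pd.DataFrame(manifest_rows).to_csv(root / "manifest.csv", index=False)
    if cohort.spec is not None:
        meta = {
            "n_patients": cohort.spec.n_patients,
            "er_prevalence": cohort.spec.er_prevalence,
            "image_size": list(cohort.spec.image_size),
            "seed": cohort.spec.seed,
        }
        (root / "cohort.json").write_text(json.dumps(meta, indent=1))


def load_cohort(directory) -> Cohort:
    """Inverse of :func:`export_cohort`."""
    root = Path(directory)
    records = {r.patient_id: r for r in cl.read_clinical_csv(root / "clinical.csv")}
    manifest = pd.read_csv(root / "manifest.csv", dtype={"patient_id": str})
    patients = []
    for pid, rec in records.items():
        areas = (
            manifest[manifest.patient_id == pid]
            .sort_values("slice")["tumor_area"]
            .tolist()
        )
        stacks = []
        n_slices = len(areas)
        for s in range(n_slices):
            phases = []
            for phase in PHASES:
                path = root / pid / phase / f"slice_{s:03d}.png"
                arr = np.asarray(Image.open(path), dtype=np.float32) / 65535.0
                phases.append(arr)
            stacks.append(np.stack(phases))
        patients.append(
            SyntheticPatient(
                pid, rec.label, np.stack(stacks).astype(np.float32), areas,
                rec, cl.encode_clinical_vector(rec),
            )
        )
    return Cohort(patients)
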