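"""Synthetic cohorts, cell tracks and IHC tables with known ground truth.

The cohort generator emulates the statistical structure the analysis
pipeline assumes in a sarcoma proteome cohort: a proteins x samples log2
abundance matrix with block-correlated latent ECM programs, subtype/grade
label structure, missing-at-random values, and exponential survival whose
hazard is tied to one named program (a proteoglycan-like protective
program by default).  Every latent quantity is returned in a truth record
so recovery can be scored without hidden state.

Model per program: sample activity a ~ Normal(mu_{subtype,grade}, 1);
member protein value = offset + sqrt(rho) * a + sqrt(1-rho) * eps with
eps ~ Normal(0, noise_sd); background proteins are i.i.d. noise.  With
noise_sd = 1 the expected pairwise Pearson correlation of two same-program
proteins is exactly rho.  Survival times are exponential with hazard
lambda * exp(beta * z), z the standardized activity of the named program,
under independent exponential censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annotations import AnnotationDB, AnnotationRecord
from .cohort_io import AbundanceMatrix, ClinicalTable, GeneSetCollection, TrackTable

# Cohort-scale defaults mirror a ~320-patient, 11-subtype sarcoma series.
DEFAULT_SUBTYPE_PROPS = {
    "AS": 30, "ASPS": 4, "CCS": 3, "DDLPS": 39, "DES": 37, "DSRCT": 4,
    "ES": 16, "LMS": 80, "RT": 12, "SS": 43, "UPS": 53,
}
DEFAULT_GRADE_PROPS = {"2": 115, "3": 139, "unknown": 67}
DEFAULT_SITE_PROPS = {
    "extremity": 125, "head_neck": 13, "intra_abdominal": 28,
    "retroperitoneal": 57, "trunk": 65, "pelvic": 24, "uterine": 9,
}
DEFAULT_DEPTH_PROPS = {"deep": 250, "superficial": 54, "unknown": 17}
DEFAULT_MARGIN_PROPS = {"R0": 133, "R1": 151, "R2": 4, "unknown": 33}
DEFAULT_SEX_PROPS = {"F": 201, "M": 119, "unknown": 1}
DEFAULT_PS_PROPS = {"0": 158, "1": 82, "2": 16, "3": 5, "unknown": 60}
DEFAULT_PREOP_PROPS = {"chemo": 19, "radio": 8, "chemo_radio": 13, "none": 267, "unknown": 14}


def _normalize(props: dict) -> dict:
    total = float(sum(props.values()))
    if total <= 0:
        raise ValueError("proportions must have a positive sum")
    return {k: v / total for k, v in props.items()}


@dataclass
class ProgramSpec:
    """One latent coregulated protein program.

    ``shifts`` maps "subtype:<label>" / "grade:<label>" keys to additive
    mean shifts of the latent activity; ``division``/``category`` place the
    member proteins in the synthetic annotation catalog.
    """

    name: str
    n_proteins: int = 60
    within_correlation: float = 0.8
    shifts: dict = field(default_factory=dict)
    division: str = "core_matrisome"
    category: str = "proteoglycans"

    def validate(self):
        if not (0.0 <= self.within_correlation < 1.0):
            raise ValueError(f"within_correlation must be in [0, 1), got {self.within_correlation}")
        if self.n_proteins < 1:
            raise ValueError("n_proteins must be >= 1")


@dataclass
class SurvivalSpec:
    """Exponential survival tied to one program's standardized activity."""

    baseline_hazard: float = 0.01        # events per month
    log_hr_per_sd: float = -0.7          # beta; negative = protective program
    program: str = "PG"
    censoring_hazard: float = 0.008      # independent exponential censoring
    effect_endpoints: tuple = ("OS",)
    endpoints: tuple = ("OS", "LRFS", "MFS")

    def validate(self):
        if self.baseline_hazard <= 0 or self.censoring_hazard <= 0:
            raise ValueError("hazards must be > 0")
        unknown = set(self.effect_endpoints) - set(self.endpoints)
        if unknown:
            raise ValueError(f"effect endpoints not generated: {sorted(unknown)}")


@dataclass
class SyntheticCohortSpec:
    n_samples: int = 300
    subtype_props: dict = field(default_factory=lambda: dict(DEFAULT_SUBTYPE_PROPS))
    grade_props: dict = field(default_factory=lambda: dict(DEFAULT_GRADE_PROPS))
    programs: list = field(default_factory=lambda: [
        ProgramSpec("ECMREG", 60, 0.8, {"grade:3": 1.0},
                    division="matrisome_associated", category="ECM_regulators"),
        ProgramSpec("BM", 60, 0.8, {"subtype:LMS": 1.2},
                    division="core_matrisome", category="glycoproteins"),
        ProgramSpec("PG", 60, 0.8, {"subtype:DES": 0.6},
                    division="core_matrisome", category="proteoglycans"),
    ])
    n_background_proteins: int = 120
    noise_sd: float = 1.0
    missing_rate: float = 0.05
    survival: SurvivalSpec = field(default_factory=SurvivalSpec)
    annotated_background_fraction: float = 0.5
    seed: int = 0

    def validate(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if not (0.0 <= self.missing_rate < 1.0):
            raise ValueError("missing_rate must be in [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        names = [p.name for p in self.programs]
        if len(set(names)) != len(names):
            raise ValueError("program names must be unique")
        for prog in self.programs:
            prog.validate()
        self.survival.validate()
        if self.survival.program not in names:
            raise ValueError(f"survival program {self.survival.program!r} not among programs")


def generate_cohort(spec: SyntheticCohortSpec | None = None, seed: int | None = None):
    """Generate (AbundanceMatrix, ClinicalTable, truth dict) from a spec.

    ``seed`` overrides ``spec.seed``; identical inputs give byte-identical
    outputs.
    """
    spec = spec or SyntheticCohortSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)

    n = spec.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]
    subtype_p = _normalize(spec.subtype_props)
    grade_p = _normalize(spec.grade_props)
    subtypes = rng.choice(list(subtype_p), size=n, p=list(subtype_p.values()))
    grades = rng.choice(list(grade_p), size=n, p=list(grade_p.values()))

    # latent program activities
    activities = pd.DataFrame(index=sample_ids, columns=[p.name for p in spec.programs],
                              dtype=float)
    for prog in spec.programs:
        mu = np.zeros(n)
        for key, shift in prog.shifts.items():
            kind, _, label = key.partition(":")
            if kind == "subtype":
                mu += shift * (subtypes == label)
            elif kind == "grade":
                mu += shift * (grades == label)
            else:
                raise ValueError(f"unknown shift key {key!r} (use 'subtype:' or 'grade:')")
        activities[prog.name] = mu + rng.standard_normal(n)

    # protein block values
    blocks, protein_ids, members = [], [], {}
    for prog in spec.programs:
        ids = [f"{prog.name}_{j + 1:03d}" for j in range(prog.n_proteins)]
        members[prog.name] = ids
        protein_ids.extend(ids)
        rho = prog.within_correlation
        offsets = rng.normal(0.0, 2.0, size=prog.n_proteins)
        eps = rng.normal(0.0, spec.noise_sd, size=(prog.n_proteins, n))
        a = activities[prog.name].to_numpy()
        blocks.append(offsets[:, None] + np.sqrt(rho) * a[None, :] + np.sqrt(1.0 - rho) * eps)
    bg_ids = [f"BG_{j + 1:03d}" for j in range(spec.n_background_proteins)]
    protein_ids.extend(bg_ids)
    if spec.n_background_proteins:
        offsets = rng.normal(0.0, 2.0, size=spec.n_background_proteins)
        blocks.append(offsets[:, None]
                      + rng.normal(0.0, spec.noise_sd, size=(spec.n_background_proteins, n)))
    values = np.vstack(blocks)

    if spec.missing_rate > 0:
        mask = rng.random(values.shape) < spec.missing_rate
        values = np.where(mask, np.nan, values)

    matrix = AbundanceMatrix(pd.DataFrame(values, index=protein_ids, columns=sample_ids))

    # survival: exponential hazard tied to the named program's activity
    sv = spec.survival
    a = activities[sv.program].to_numpy()
    z = (a - a.mean()) / a.std(ddof=0)
    clin = {
        "subtype": subtypes, "grade": grades,
        "site": rng.choice(list(_normalize(DEFAULT_SITE_PROPS)), size=n,
                           p=list(_normalize(DEFAULT_SITE_PROPS).values())),
        "depth": rng.choice(list(_normalize(DEFAULT_DEPTH_PROPS)), size=n,
                            p=list(_normalize(DEFAULT_DEPTH_PROPS).values())),
        "margins": rng.choice(list(_normalize(DEFAULT_MARGIN_PROPS)), size=n,
                              p=list(_normalize(DEFAULT_MARGIN_PROPS).values())),
        "sex": rng.choice(list(_normalize(DEFAULT_SEX_PROPS)), size=n,
                          p=list(_normalize(DEFAULT_SEX_PROPS).values())),
        "performance_status": rng.choice(list(_normalize(DEFAULT_PS_PROPS)), size=n,
                                         p=list(_normalize(DEFAULT_PS_PROPS).values())),
        "preop_treatment": rng.choice(list(_normalize(DEFAULT_PREOP_PROPS)), size=n,
                                      p=list(_normalize(DEFAULT_PREOP_PROPS).values())),
        "tumor_size": np.clip(rng.lognormal(np.log(90.0), 0.7, size=n), 4, None).round(1),
        "age": np.clip(rng.normal(56.0, 18.0, size=n), 1, 90).round(1),
    }
    table = pd.DataFrame(clin, index=sample_ids)
    table.index.name = "sample_id"
    linear_predictor = sv.log_hr_per_sd * z
    for label in sv.endpoints:
        lp = linear_predictor if label in sv.effect_endpoints else np.zeros(n)
        event_t = rng.exponential(1.0 / (sv.baseline_hazard * np.exp(lp)))
        censor_t = rng.exponential(1.0 / sv.censoring_hazard, size=n)
        table[f"{label}_time"] = np.minimum(event_t, censor_t).round(3)
        table[f"{label}_event"] = (event_t <= censor_t).astype(int)
    clinical = ClinicalTable(table)

    truth = {
        "activities": activities,
        "program_members": members,
        "background_proteins": bg_ids,
        "linear_predictor": pd.Series(linear_predictor, index=sample_ids),
        "spec": asdict(spec),
    }
    return matrix, clinical, truth


def synthetic_catalog(spec: SyntheticCohortSpec | None = None) -> AnnotationDB:
    """Annotation catalog matching a synthetic cohort's protein ids.

    Program proteins get their program's division/category; the first
    ``annotated_background_fraction`` of background proteins are annotated
    as adhesome adaptors, the rest stay outside the catalog so filtering
    is non-trivial.
    """
    spec = spec or SyntheticCohortSpec()
    spec.validate()
    records = []
    for prog in spec.programs:
        for j in range(prog.n_proteins):
            records.append(AnnotationRecord(f"{prog.name}_{j + 1:03d}", prog.division, prog.category))
    n_annot = int(round(spec.annotated_background_fraction * spec.n_background_proteins))
    for j in range(n_annot):
        records.append(AnnotationRecord(f"BG_{j + 1:03d}", "adhesome", "adaptor"))
    return AnnotationDB(records, source_version="synthetic-cohort-catalog")


def truth_genesets(truth: dict, n_decoys: int = 0, decoy_size: int = 11,
                   seed: int = 0) -> GeneSetCollection:
    """Gene sets for the program members, optionally plus background decoys."""
    sets = {name: list(m) for name, m in truth["program_members"].items()}
    desc = {name: "latent program members" for name in sets}
    if n_decoys:
        rng = np.random.default_rng(seed)
        pool = list(truth["background_proteins"])
        if decoy_size > len(pool):
            raise ValueError("decoy_size exceeds background pool")
        for d in range(n_decoys):
            picks = rng.choice(pool, size=decoy_size, replace=False)
            sets[f"DECOY_{d + 1:02d}"] = sorted(picks)
            desc[f"DECOY_{d + 1:02d}"] = "background decoy set"
    return GeneSetCollection(sets, desc)


# ---------------------------------------------------------------------------
# Cell tracks


@dataclass
class SyntheticTrackSpec:
    """Persistent-random-walk tracks (heading diffusion + Rayleigh steps)."""

    n_tracks: int = 100
    n_frames: int = 37               # every 30 min for 18 h
    frame_interval: float = 30.0     # minutes
    step_scale: float = 2.0          # Rayleigh sigma, micrometres per frame
    angular_noise: float = 0.5       # SD of heading increments, radians
    condition: str = "plastic"
    seed: int = 0

    def validate(self):
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.step_scale <= 0:
            raise ValueError("step_scale must be > 0")
        if self.angular_noise < 0:
            raise ValueError("angular_noise must be >= 0")


def generate_tracks(spec: SyntheticTrackSpec | None = None, seed: int | None = None) -> TrackTable:
    """Persistent random walk: wrapped-normal heading increments, Rayleigh steps."""
    spec = spec or SyntheticTrackSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    rows = []
    n_steps = spec.n_frames - 1
    for tid in range(spec.n_tracks):
        heading0 = rng.uniform(0.0, 2.0 * np.pi)
        increments = rng.normal(0.0, spec.angular_noise, size=n_steps) if spec.angular_noise > 0 \
            else np.zeros(n_steps)
        headings = heading0 + np.cumsum(increments)
        steps = rng.rayleigh(spec.step_scale, size=n_steps)
        dx = steps * np.cos(headings)
        dy = steps * np.sin(headings)
        x = np.concatenate([[0.0], np.cumsum(dx)])
        y = np.concatenate([[0.0], np.cumsum(dy)])
        for f in range(spec.n_frames):
            rows.append({
                "track_id": f"T{tid + 1:04d}", "frame": f,
                "t": f * spec.frame_interval, "x": x[f], "y": y[f],
                "condition": spec.condition,
            })
    return TrackTable(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# IHC cell tables


@dataclass
class SyntheticIhcSpec:
    """Per-core DAB optical densities from a lognormal mixture."""

    n_cores: int = 30
    cells_per_core: int = 200
    # (weight, median OD, sigma of log OD) per staining component
    components: tuple = ((0.4, 0.08, 0.3), (0.3, 0.16, 0.2), (0.3, 0.30, 0.2))
    seed: int = 0

    def validate(self):
        w = np.array([c[0] for c in self.components], dtype=float)
        if (w < 0).any() or w.sum() <= 0:
            raise ValueError("component weights must be non-negative with positive sum")
        if any(c[1] <= 0 or c[2] <= 0 for c in self.components):
            raise ValueError("component medians and sigmas must be > 0")


def generate_ihc(spec: SyntheticIhcSpec | None = None, seed: int | None = None) -> pd.DataFrame:
    """Cell measurement table with columns core_id, cell_id, od."""
    spec = spec or SyntheticIhcSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    weights = np.array([c[0] for c in spec.components], dtype=float)
    weights = weights / weights.sum()
    rows = []
    for core in range(spec.n_cores):
        comp = rng.choice(len(spec.components), size=spec.cells_per_core, p=weights)
        for cell in range(spec.cells_per_core):
            _, med, sig = spec.components[comp[cell]]
            od = rng.lognormal(np.log(med), sig)
            rows.append({"core_id": f"C{core + 1:03d}", "cell_id": f"cell{cell + 1:04d}",
                         "od": od})
    return pd.DataFrame(rows)
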