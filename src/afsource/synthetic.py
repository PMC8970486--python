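"""Seeded synthetic AF corpus generator.

Produces labeled multichannel surface-potential episodes of the four
study categories — driver-type focal source (FS), initiator-type FS,
FS-induced AF, and reentrant AF — with the statistical structure the
classifiers exploit:

* periodic activation-like dipole sources with cycle lengths in the
  clinical 120-270 ms range, optional 2:1 conduction block (which doubles
  the effective beat spacing) and cycle-to-cycle drift for fibrillatory
  sources;
* an infinite-homogeneous-medium dipole-sum forward model projecting the
  sources onto a 252-electrode torso vest (quasi-uniform cylinder
  geometry) from which a 12-lead ECG can be derived;
* additive white noise at a configurable SNR and rigid vest-placement
  perturbations (rotation about the torso axis, translation);
* an experiment-design enumerator reproducing the study bookkeeping
  (36 focal sites x 6 CLs x 2 ACh levels per patient; 32 reentry core
  sites x 3 radii x 2 ACh levels);
* analytic spiral-wave phase movies with a known core trajectory, the
  ground-truth fixture for phase-singularity detection and tracking.

Episode categories differ in source composition: a driver-type FS is a
jitter-free focal dipole with fully CL-synchronized satellites; an
initiator-type FS adds a desynchronized (CL difference > 10 ms) drifting
reentrant source; FS-induced AF keeps only the parent initiator's
reentrant sources (focal ablation); reentrant AF has drifting reentrant
sources only. Which FS configurations become initiators is decided by a
seeded inducibility policy whose per-chamber/per-CL probabilities peak at
CL 180 ms for LA/PV foci and 210 ms for RA foci, mimicking the simulated
inducibility profile in shape only.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .classify import AtrialSite, EpisodeLabel
from .signal_io import ECG_ROLES, ElectrodeArray, MultichannelSignal
from .tissue_analysis import PhaseField

__all__ = [
    "ExperimentDesign",
    "SourceSpec",
    "EpisodeRecipe",
    "Corpus",
    "enumerate_design",
    "gen_source_waveform",
    "phi_e_forward",
    "gen_episode",
    "perturb_vest",
    "gen_spiral_phase_movie",
    "build_corpus",
    "default_corpus",
    "cylinder_vest",
    "default_inducibility",
]

UAC_GRID = (0.2, 0.4, 0.6, 0.8)
PV_NAMES = ("LSPV", "LIPV", "RSPV", "RIPV")
DEFAULT_CLS_MS = (120.0, 150.0, 180.0, 210.0, 240.0, 270.0)


# ---------------------------------------------------------------------------
# Experiment design


@dataclass(frozen=True)
class ExperimentDesign:
    """The full factorial study layout.

    Focal sources: 16 (alpha, beta) grid sites per atrium plus 4 pulmonary
    veins = 36 sites, each paced at 6 cycle lengths with and without ACh.
    Reentry: inexcitable cores of 3 radii at the 32 grid sites, with and
    without ACh.
    """

    patients: tuple = ("p1", "p2", "p3", "p4", "p5")
    cls_ms: tuple = DEFAULT_CLS_MS
    ach_levels: tuple = (False, True)
    core_radii_cm: tuple = (0.0, 0.5, 1.0)

    def fs_sites(self) -> list[AtrialSite]:
        sites = [
            AtrialSite(chamber=ch, alpha=a, beta=b)
            for ch in ("LA", "RA")
            for a in UAC_GRID
            for b in UAC_GRID
        ]
        sites += [AtrialSite(chamber="PV", vein=v) for v in PV_NAMES]
        return sites

    def reentry_sites(self) -> list[AtrialSite]:
        return [
            AtrialSite(chamber=ch, alpha=a, beta=b)
            for ch in ("LA", "RA")
            for a in UAC_GRID
            for b in UAC_GRID
        ]


def _site_key(site: AtrialSite) -> str:
    if site.chamber == "PV":
        return f"PV:{site.vein}"
    return f"{site.chamber}:{site.alpha:.1f},{site.beta:.1f}"


def enumerate_design(d: ExperimentDesign) -> dict:
    """One row per configuration, deterministically ordered.

    Returns ``{"fs": DataFrame, "reentry": DataFrame}``; for the default
    5-patient design that is 5 x 36 x 6 x 2 = 2160 focal configurations
    and 5 x 32 x 3 x 2 = 960 reentry configurations.
    """
    fs_rows = [
        {
            "patient_id": p,
            "site": _site_key(s),
            "chamber": s.chamber,
            "cl_ms": cl,
            "ach": ach,
        }
        for p, s, cl, ach in itertools.product(
            d.patients, d.fs_sites(), d.cls_ms, d.ach_levels
        )
    ]
    re_rows = [
        {
            "patient_id": p,
            "site": _site_key(s),
            "chamber": s.chamber,
            "core_radius_cm": r,
            "ach": ach,
        }
        for p, s, r, ach in itertools.product(
            d.patients, d.reentry_sites(), d.core_radii_cm, d.ach_levels
        )
    ]
    return {"fs": pd.DataFrame(fs_rows), "reentry": pd.DataFrame(re_rows)}


# ---------------------------------------------------------------------------
# Electrode geometry


def cylinder_vest(
    n_electrodes: int = 252,
    radius_cm: float = 15.0,
    height_cm: float = 40.0,
) -> ElectrodeArray:
    """Quasi-uniform electrode vest on a torso-sized cylinder.

    Electrodes are laid out on rings around the vertical (z) axis. The
    9-electrode ECG subset (RA, LA, LL, V1-V6) is assigned to the vest
    points nearest the conventional torso positions.
    """
    n_rows = max(int(round(np.sqrt(n_electrodes * height_cm / (2 * np.pi * radius_cm)))), 2)
    per_row = n_electrodes // n_rows
    extras = n_electrodes - n_rows * per_row
    pos = []
    zs = np.linspace(-height_cm / 2, height_cm / 2, n_rows)
    for i, z in enumerate(zs):
        m = per_row + (1 if i < extras else 0)
        # stagger alternate rings for quasi-uniform coverage
        offs = (i % 2) * np.pi / m
        ang = offs + 2 * np.pi * np.arange(m) / m
        for a in ang:
            pos.append((radius_cm * np.cos(a), radius_cm * np.sin(a), z))
    pos = np.asarray(pos)
    labels = tuple(f"E{i:03d}" for i in range(len(pos)))

    # canonical torso landmarks (x: patient-right +, y: anterior +, z: up)
    r = radius_cm
    landmarks = {
        "RA": (0.7 * r, 0.5 * r, 0.45 * height_cm),
        "LA": (-0.7 * r, 0.5 * r, 0.45 * height_cm),
        "LL": (-0.6 * r, 0.3 * r, -0.45 * height_cm),
        "V1": (0.15 * r, 0.95 * r, 0.1 * height_cm),
        "V2": (-0.15 * r, 0.95 * r, 0.1 * height_cm),
        "V3": (-0.3 * r, 0.9 * r, 0.05 * height_cm),
        "V4": (-0.45 * r, 0.8 * r, 0.0),
        "V5": (-0.6 * r, 0.65 * r, 0.0),
        "V6": (-0.75 * r, 0.45 * r, 0.0),
    }
    subset = {}
    taken: set[int] = set()
    for role in ECG_ROLES:
        d2 = np.sum((pos - np.asarray(landmarks[role])) ** 2, axis=1)
        for idx in np.argsort(d2):
            if int(idx) not in taken:
                subset[role] = int(idx)
                taken.add(int(idx))
                break
    return ElectrodeArray(positions=pos, labels=labels, ecg_subset=subset)


def perturb_vest(
    electrodes: ElectrodeArray,
    rot_deg_z: float = 0.0,
    shift_cm_xyz=(0.0, 0.0, 0.0),
) -> ElectrodeArray:
    """Rigidly rotate the vest about the z axis through its centroid, then
    translate. Labels and the ECG subset are preserved."""
    pos = electrodes.positions
    centroid = pos.mean(axis=0)
    th = np.deg2rad(rot_deg_z)
    R = np.array(
        [[np.cos(th), -np.sin(th), 0.0],
         [np.sin(th), np.cos(th), 0.0],
         [0.0, 0.0, 1.0]]
    )
    out = (pos - centroid) @ R.T + centroid + np.asarray(shift_cm_xyz, dtype=float)
    return ElectrodeArray(
        positions=out, labels=electrodes.labels, ecg_subset=dict(electrodes.ecg_subset)
    )


# ---------------------------------------------------------------------------
# Sources and waveforms


@dataclass(frozen=True)
class SourceSpec:
    """One equivalent periodic source: a dipole firing a pulse train."""

    cl_ms: float
    origin_cm: tuple = (0.0, 0.0, 0.0)
    chamber: str = "LA"
    waveform: str = "pulse_train"  # pulse_train | sinusoid
    jitter_ms: float = 0.0
    block_ratio: str = "1:1"  # 2:1 drops every other beat
    drift_ms: float = 0.0  # cycle-to-cycle CL drift s.d.
    amplitude: float = 1.0
    phase_ms: float = 0.0

    def __post_init__(self):
        if self.cl_ms <= 0:
            raise ValueError("cl_ms must be positive")
        if self.block_ratio not in ("1:1", "2:1"):
            raise ValueError(f"unknown block ratio {self.block_ratio!r}")
        if self.waveform not in ("pulse_train", "sinusoid"):
            raise ValueError(f"unknown waveform {self.waveform!r}")

    @property
    def effective_cl_ms(self) -> float:
        """Beat spacing after conduction block (2:1 doubles the CL)."""
        return self.cl_ms * (2.0 if self.block_ratio == "2:1" else 1.0)


def gen_source_waveform(
    spec: SourceSpec,
    duration_ms: float,
    fs: float,
    seed: int | np.random.Generator = 0,
    pulse_width_ms: float = 40.0,
) -> np.ndarray:
    """Unit-RMS activation waveform of one source.

    ``pulse_train`` places a Gaussian-derivative wavelet (width
    ``pulse_width_ms``) at every beat; beats are spaced by the effective
    CL with optional Gaussian timing jitter and cycle-to-cycle drift.
    A 2:1 conduction block drops alternate beats, doubling the spacing.
    """
    if duration_ms < 2 * spec.cl_ms:
        raise ValueError(
            f"duration {duration_ms} ms too short for CL {spec.cl_ms} ms"
        )
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    T = int(round(duration_ms * fs / 1000.0))
    t = np.arange(T) / fs * 1000.0  # ms
    ecl = spec.effective_cl_ms
    if spec.waveform == "sinusoid":
        x = np.sin(2 * np.pi * (t - spec.phase_ms) / ecl)
    else:
        sigma = pulse_width_ms / 4.0
        # beat times with drift accumulating cycle to cycle
        beats = []
        bt = float(spec.phase_ms % ecl) - ecl
        while bt < duration_ms + 2 * pulse_width_ms:
            beats.append(bt + rng.normal(0.0, spec.jitter_ms) if spec.jitter_ms else bt)
            bt += ecl + (rng.normal(0.0, spec.drift_ms) if spec.drift_ms else 0.0)
        x = np.zeros(T)
        for b in beats:
            u = (t - b) / sigma
            near = np.abs(u) < 6.0
            x[near] += -u[near] * np.exp(-0.5 * u[near] ** 2)
    rms = np.sqrt(np.mean(x**2))
    if rms == 0.0:
        raise ValueError("generated waveform is identically zero")
    return x / rms


# ---------------------------------------------------------------------------
# Forward model


def phi_e_forward(
    source_positions_cm: np.ndarray,
    source_moments: np.ndarray,
    electrodes: ElectrodeArray,
    sigma_s_per_m: float = 0.2,
    fs: float = 1000.0,
    min_distance_cm: float = 0.5,
) -> MultichannelSignal:
    """Extracellular potentials of time-varying dipoles at the electrodes.

    Infinite homogeneous medium:
    ``phi_e(r) = (1 / 4 pi sigma) sum_i p_i . (r - r_i) / |r - r_i|^3``.
    ``source_moments`` has shape (n, 3, T) (dipole moment vector over
    time); the result is linear in the moments.
    """
    rs = np.atleast_2d(np.asarray(source_positions_cm, dtype=float))
    p = np.asarray(source_moments, dtype=float)
    if p.ndim != 3 or p.shape[0] != rs.shape[0] or p.shape[1] != 3:
        raise ValueError("source_moments must have shape (n_sources, 3, T)")
    re = electrodes.positions  # (L, 3) cm
    diff = re[:, None, :] - rs[None, :, :]  # (L, n, 3)
    dist = np.linalg.norm(diff, axis=2)  # (L, n)
    if np.any(dist < min_distance_cm):
        raise ValueError(
            f"electrode-source distance below {min_distance_cm} cm"
        )
    # lead-field gain (L, n, 3) in 1/cm^2; sigma in S/m -> convert cm
    gain = diff / dist[:, :, None] ** 3 / (4 * np.pi * sigma_s_per_m * 1e-2)
    data = np.einsum("lnc,nct->lt", gain, p)  # (L, T)
    return MultichannelSignal(
        data=data.T, fs=fs, lead_labels=electrodes.labels
    )


# ---------------------------------------------------------------------------
# Episodes


@dataclass(frozen=True)
class EpisodeRecipe:
    """Full description of one synthetic episode."""

    category: str
    focal: SourceSpec | None = None
    reentrant: tuple = ()
    snr_db: float = 20.0
    duration_ms: float = 1000.0
    fs: float = 1000.0
    seed: int = 0
    patient_id: str = "p0"
    segment_id: str = "s0"
    site: AtrialSite | None = None
    ach: bool = False
    parent_segment_id: str | None = None

    def __post_init__(self):
        object.__setattr__(self, "reentrant", tuple(self.reentrant))
        if self.category in ("driver_fs", "initiator_fs"):
            if self.focal is None:
                raise ValueError(f"{self.category} recipe needs a focal source")
            if self.category == "driver_fs":
                for r in self.reentrant:
                    if abs(r.cl_ms - self.focal.cl_ms) > 1e-9:
                        raise ValueError(
                            "driver_fs satellites must be CL-synchronized"
                        )
            else:
                if not any(
                    abs(r.cl_ms - self.focal.cl_ms) > 10.0 for r in self.reentrant
                ):
                    raise ValueError(
                        "initiator_fs needs a reentrant source with CL "
                        "differing by > 10 ms"
                    )
        elif self.category in ("fs_induced_af", "reentrant_af"):
            if self.focal is not None:
                raise ValueError(f"{self.category} recipe must have no focal source")
            if not self.reentrant:
                raise ValueError(f"{self.category} recipe needs reentrant sources")
        else:
            raise ValueError(f"unknown category {self.category!r}")

    def all_sources(self) -> tuple:
        return ((self.focal,) if self.focal is not None else ()) + self.reentrant


def gen_episode(
    recipe: EpisodeRecipe, electrodes: ElectrodeArray
) -> tuple[MultichannelSignal, EpisodeLabel]:
    """Render a recipe to surface potentials plus its ground-truth label.

    Each source becomes a dipole at its origin with a fixed (seeded)
    orientation and its activation waveform as moment magnitude; the
    potentials are the dipole-sum forward solution plus white noise at
    the recipe's SNR.
    """
    rng = np.random.default_rng(recipe.seed)
    sources = recipe.all_sources()
    T = int(round(recipe.duration_ms * recipe.fs / 1000.0))
    moments = np.zeros((len(sources), 3, T))
    positions = np.zeros((len(sources), 3))
    for i, src in enumerate(sources):
        ori = rng.normal(size=3)
        ori /= np.linalg.norm(ori)
        w = gen_source_waveform(src, recipe.duration_ms, recipe.fs, rng)
        moments[i] = src.amplitude * ori[:, None] * w[None, :]
        positions[i] = src.origin_cm
    sig = phi_e_forward(positions, moments, electrodes, fs=recipe.fs)
    if np.isfinite(recipe.snr_db):
        rms = np.sqrt(np.mean(sig.data**2))
        noise_sd = rms * 10.0 ** (-recipe.snr_db / 20.0)
        sig = replace(sig, data=sig.data + rng.normal(0.0, noise_sd, sig.data.shape))
    label = EpisodeLabel(
        category=recipe.category,
        patient_id=recipe.patient_id,
        segment_id=recipe.segment_id,
        focal_site=recipe.site if recipe.focal is not None else None,
        focal_cl_ms=recipe.focal.cl_ms if recipe.focal is not None else None,
        ach=recipe.ach,
        parent_segment_id=recipe.parent_segment_id,
    )
    return sig, label


# ---------------------------------------------------------------------------
# Atrial geometry for synthetic sources

_CHAMBER_CENTER_CM = {
    "RA": np.array([4.0, 2.0, 0.0]),
    "LA": np.array([-4.0, 2.0, 0.0]),
    "PV": np.array([-6.5, -1.0, 1.0]),
}
_PV_OFFSET_CM = {
    "LSPV": np.array([-1.0, 0.0, 1.5]),
    "LIPV": np.array([-1.0, 0.0, -1.5]),
    "RSPV": np.array([1.0, 0.0, 1.5]),
    "RIPV": np.array([1.0, 0.0, -1.5]),
}


def site_position_cm(site: AtrialSite) -> np.ndarray:
    """Map a focal site to a 3-D position inside the torso."""
    c = _CHAMBER_CENTER_CM[site.chamber].copy()
    if site.chamber == "PV":
        return c + _PV_OFFSET_CM[site.vein]
    return c + np.array(
        [(site.alpha - 0.5) * 4.0, (site.beta - 0.5) * 2.0, (site.beta - 0.5) * 3.0]
    )


# ---------------------------------------------------------------------------
# Inducibility policy and corpus assembly


def default_inducibility() -> dict:
    """Probability that an FS configuration induces sustained AF.

    Shapes follow the simulated profile qualitatively: inducibility peaks
    at CL 180 ms for LA and PV foci and at CL 210 ms for RA foci, and ACh
    raises LA inducibility at 150-210 ms and PV inducibility at 150 ms.
    Not a claim of biophysical fidelity.
    """
    base = {
        "LA": {120: 0.00, 150: 0.55, 180: 0.88, 210: 0.35, 240: 0.10, 270: 0.00},
        "PV": {120: 0.05, 150: 0.60, 180: 0.95, 210: 0.50, 240: 0.15, 270: 0.00},
        "RA": {120: 0.00, 150: 0.05, 180: 0.10, 210: 0.24, 240: 0.05, 270: 0.00},
    }
    ach_bonus = {
        "LA": {150: 0.15, 180: 0.07, 210: 0.15},
        "PV": {150: 0.15},
        "RA": {},
    }
    return {"base": base, "ach_bonus": ach_bonus}


def _inducibility_p(policy: dict, chamber: str, cl_ms: float, ach: bool) -> float:
    cl = int(round(cl_ms))
    p = policy["base"][chamber].get(cl, 0.0)
    if ach:
        p = min(p + policy["ach_bonus"][chamber].get(cl, 0.0), 1.0)
    return p


@dataclass
class Corpus:
    """Generated study corpus: signals, labels, manifest, geometry."""

    signals: list
    labels: list
    electrodes: ElectrodeArray
    manifest: pd.DataFrame
    recipes: list = field(default_factory=list)


def _fs_recipe(
    category: str,
    site: AtrialSite,
    cl: float,
    ach: bool,
    patient_id: str,
    segment_id: str,
    seed: int,
    rng: np.random.Generator,
    snr_db: float,
) -> EpisodeRecipe:
    origin = tuple(site_position_cm(site))
    block = "2:1" if (cl <= 150.0 and rng.random() < 0.3) else "1:1"
    focal = SourceSpec(
        cl_ms=cl, origin_cm=origin, chamber=site.chamber, block_ratio=block
    )
    jitter = lambda: tuple(np.asarray(origin) + rng.normal(0.0, 1.0, 3))
    satellites = tuple(
        SourceSpec(
            cl_ms=cl,
            origin_cm=jitter(),
            chamber=site.chamber,
            block_ratio=block,
            amplitude=0.6,
            phase_ms=float(rng.uniform(0, cl)),
        )
        for _ in range(2)
    )
    if category == "driver_fs":
        return EpisodeRecipe(
            category="driver_fs", focal=focal, reentrant=satellites,
            seed=seed, patient_id=patient_id, segment_id=segment_id,
            site=site, ach=ach, snr_db=snr_db,
        )
    # initiator: one satellite plus a desynchronized drifting reentrant source
    re_cl = float(rng.choice([c for c in DEFAULT_CLS_MS if abs(c - cl) > 10.0]))
    re_cl += float(rng.uniform(-8.0, 8.0))
    re_site = AtrialSite(
        chamber=rng.choice(["LA", "RA"]),
        alpha=float(rng.choice(UAC_GRID)),
        beta=float(rng.choice(UAC_GRID)),
    )
    reentrant = SourceSpec(
        cl_ms=re_cl,
        origin_cm=tuple(site_position_cm(re_site)),
        chamber=re_site.chamber,
        drift_ms=3.0,
        amplitude=0.8,
        phase_ms=float(rng.uniform(0, re_cl)),
    )
    return EpisodeRecipe(
        category="initiator_fs", focal=focal, reentrant=satellites[:1] + (reentrant,),
        seed=seed, patient_id=patient_id, segment_id=segment_id,
        site=site, ach=ach, snr_db=snr_db,
    )


def _reentrant_recipe(
    category: str,
    base_sources: tuple,
    patient_id: str,
    segment_id: str,
    seed: int,
    rng: np.random.Generator,
    snr_db: float,
    ach: bool,
    parent: str | None = None,
) -> EpisodeRecipe:
    return EpisodeRecipe(
        category=category,
        reentrant=base_sources,
        seed=seed,
        patient_id=patient_id,
        segment_id=segment_id,
        ach=ach,
        snr_db=snr_db,
        parent_segment_id=parent,
    )


def build_corpus(
    design: ExperimentDesign | None = None,
    policy: dict | None = None,
    seed: int = 0,
    per_patient_fs: int = 48,
    per_patient_reentry: int = 24,
    snr_db: float = 20.0,
    electrodes: ElectrodeArray | None = None,
    duration_ms: float = 1000.0,
    fs: float = 1000.0,
) -> Corpus:
    """Assemble a seeded labeled corpus of the four episode categories.

    Per patient, ``per_patient_fs`` focal configurations are sampled from
    the design without replacement; each becomes a driver-type or
    initiator-type FS episode according to the inducibility policy, and
    every initiator is paired with exactly one FS-induced-AF segment
    (its reentrant sources after focal ablation). ``per_patient_reentry``
    reentry configurations yield reentrant-AF episodes.
    """
    if design is None:
        design = ExperimentDesign()
    if policy is None:
        policy = default_inducibility()
    if electrodes is None:
        electrodes = cylinder_vest()
    rng = np.random.default_rng(seed)

    fs_sites = design.fs_sites()
    re_sites = design.reentry_sites()
    fs_configs = list(itertools.product(fs_sites, design.cls_ms, design.ach_levels))
    signals, labels, recipes, rows = [], [], [], []

    for p_idx, patient in enumerate(design.patients):
        # per-patient inducibility scaling emulates inter-patient variability
        patient_factor = float(rng.uniform(0.8, 1.2))
        pick = rng.choice(len(fs_configs), size=min(per_patient_fs, len(fs_configs)),
                          replace=False)
        seg = 0
        for ci in pick:
            site, cl, ach = fs_configs[ci]
            p_ind = min(_inducibility_p(policy, site.chamber, cl, ach) * patient_factor, 1.0)
            induced = rng.random() < p_ind
            category = "initiator_fs" if induced else "driver_fs"
            seg_id = f"{patient}_fs{seg:03d}"
            ep_seed = int(rng.integers(0, 2**31 - 1))
            recipe = _fs_recipe(
                category, site, cl, ach, patient, seg_id, ep_seed, rng, snr_db
            )
            recipe = replace(recipe, duration_ms=duration_ms, fs=fs)
            sig, lab = gen_episode(recipe, electrodes)
            signals.append(sig); labels.append(lab); recipes.append(recipe)
            rows.append({"segment_id": seg_id, "patient_id": patient,
                         "category": category, "site": _site_key(site),
                         "cl_ms": cl, "ach": ach})
            seg += 1
            if induced:
                # paired FS-induced AF: the initiator's reentrant sources
                # continue after focal ablation
                af_id = f"{patient}_fs{seg:03d}"
                drifting = tuple(
                    replace(s, drift_ms=max(s.drift_ms, 3.0),
                            phase_ms=float(rng.uniform(0, s.cl_ms)))
                    for s in recipe.reentrant if s.drift_ms > 0
                ) or (replace(recipe.reentrant[-1], drift_ms=3.0),)
                af_recipe = _reentrant_recipe(
                    "fs_induced_af", drifting, patient, af_id,
                    int(rng.integers(0, 2**31 - 1)), rng, snr_db, ach,
                    parent=seg_id,
                )
                af_recipe = replace(af_recipe, duration_ms=duration_ms, fs=fs)
                sig, lab = gen_episode(af_recipe, electrodes)
                signals.append(sig); labels.append(lab); recipes.append(af_recipe)
                rows.append({"segment_id": af_id, "patient_id": patient,
                             "category": "fs_induced_af", "site": _site_key(site),
                             "cl_ms": np.nan, "ach": ach})
                seg += 1
        re_pick = rng.choice(len(re_sites), size=min(per_patient_reentry, len(re_sites) * 2),
                             replace=True)
        for si in re_pick:
            site = re_sites[si]
            ach = bool(rng.random() < 0.5)
            seg_id = f"{patient}_re{seg:03d}"
            n_src = int(rng.integers(2, 4))
            cls_pick = rng.choice(DEFAULT_CLS_MS, size=n_src, replace=False)
            srcs = tuple(
                SourceSpec(
                    cl_ms=float(c) + float(rng.uniform(-8, 8)),
                    origin_cm=tuple(
                        site_position_cm(site) + rng.normal(0.0, 1.5, 3)
                    ),
                    chamber=site.chamber,
                    drift_ms=3.0,
                    amplitude=float(rng.uniform(0.6, 1.0)),
                    phase_ms=float(rng.uniform(0, c)),
                )
                for c in cls_pick
            )
            recipe = _reentrant_recipe(
                "reentrant_af", srcs, patient, seg_id,
                int(rng.integers(0, 2**31 - 1)), rng, snr_db, ach,
            )
            recipe = replace(recipe, duration_ms=duration_ms, fs=fs)
            sig, lab = gen_episode(recipe, electrodes)
            signals.append(sig); labels.append(lab); recipes.append(recipe)
            rows.append({"segment_id": seg_id, "patient_id": patient,
                         "category": "reentrant_af", "site": _site_key(site),
                         "cl_ms": np.nan, "ach": ach})
            seg += 1

    manifest = pd.DataFrame(rows)
    return Corpus(
        signals=signals, labels=labels, electrodes=electrodes,
        manifest=manifest, recipes=recipes,
    )


def default_corpus(seed: int = 0) -> Corpus:
    """The default study corpus: 5 virtual patients, ~400 one-second
    episodes at 1 kHz on the 252-electrode vest, SNR 20 dB."""
    return build_corpus(seed=seed)


# ---------------------------------------------------------------------------
# Analytic spiral phase movies


def gen_spiral_phase_movie(
    core_path,
    omega: float,
    k: float,
    grid_shape: tuple = (100, 100),
    spacing_mm: float = 1.0,
    fs: float = 1000.0,
    n_frames: int = 300,
) -> PhaseField:
    """Analytic Archimedean-spiral phase movie with a known core.

    ``phi(x, y, t) = s*atan2(y - yc(t), x - xc(t)) - k*r - omega*t`` with
    ``s = sign(omega)``, wrapped to (-pi, pi]. ``core_path`` maps the
    frame time in ms to the core (x, y) in mm and must stay at least two
    cells inside the grid; the sign of ``omega`` sets the chirality.
    """
    s = 1.0 if omega >= 0 else -1.0
    ny, nx = grid_shape
    ys, xs = np.meshgrid(
        np.arange(ny) * spacing_mm, np.arange(nx) * spacing_mm, indexing="ij"
    )
    margin = 2 * spacing_mm
    phase = np.empty((ny * nx, n_frames))
    for f in range(n_frames):
        t_ms = f / fs * 1000.0
        xc, yc = core_path(t_ms)
        if not (margin <= xc <= (nx - 1) * spacing_mm - margin
                and margin <= yc <= (ny - 1) * spacing_mm - margin):
            raise ValueError(f"spiral core leaves the grid at frame {f}")
        dx, dy = xs - xc, ys - yc
        r = np.hypot(dx, dy)
        ph = s * np.arctan2(dy, dx) - k * r - omega * t_ms / 1000.0
        phase[:, f] = np.angle(np.exp(1j * ph)).ravel()
    return PhaseField(
        phase=phase,
        fs=fs,
        mask=np.ones(ny * nx, dtype=bool),
        grid_shape=grid_shape,
        spacing_mm=spacing_mm,
    )
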