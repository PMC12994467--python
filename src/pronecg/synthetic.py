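"""Synthetic paired-posture cohort generator.

The physical premise of prone-to-standard conversion is that the cardiac
dipole loop (the VCG) does not depend on body position; only the lead
fields through which it is observed do.  The generator therefore builds,
per subject, a single dipole trajectory as a sum of Gaussian kernels (one
per wave: P, Q, R, S, optional ST offset, T) and projects it through two
linear 12x3 lead-field matrices - one supine, one prone - to obtain the
paired ECGs.  Disease classes perturb the kernels (ST loop offsets, lost
initial QRS forces, widened QRS with terminal delay, frontal-axis
rotation), emulating the cohort's diagnosis mix.

The prone field is a stylised stand-in for the true (unpublished) prone
electrode geometry: precordial rows are mirrored/sign-flipped so that
standard V1 pairs inversely with prone V4, V2 with prone V2 and V4 with
prone V1, while prone V6 keeps the standard V6 row (same anatomical site)
and limb-lead rows are posture-invariant.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .delineation import BeatFiducials
from .errors import ConfigError
from .records import (
    LEAD_NAMES,
    DiagnosisLabel,
    ECGRecord,
    Posture,
    SubjectCovariates,
    VCGRecord,
)
from .transforms import DOWER, UIJEN, TransformMatrix


# ---------------------------------------------------------------------------
# Dipole kernels and beat shape
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Kernel:
    """One Gaussian dipole component: vec * exp(-(t-mu)^2 / 2 sigma^2)."""

    name: str
    vec: tuple[float, float, float]  # mV along (X, Y, Z)
    mu: float                        # centre, seconds from beat onset
    sigma: float                     # width, seconds

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        g = np.exp(-((t - self.mu) ** 2) / (2.0 * self.sigma**2))
        return np.outer(np.asarray(self.vec), g)


QRS_KERNELS = ("Q", "R", "S", "QRSterm")


@dataclass
class BeatShapeParams:
    """Kernel set describing one subject's beat-level dipole loop."""

    kernels: list[Kernel]

    @classmethod
    def default(cls) -> "BeatShapeParams":
        return cls(kernels=[
            Kernel("P", (0.04, 0.10, -0.015), 0.150, 0.022),
            Kernel("Q", (-0.08, -0.04, 0.10), 0.285, 0.009),
            Kernel("R", (0.95, 0.65, -0.40), 0.305, 0.011),
            Kernel("S", (-0.30, -0.20, 0.45), 0.327, 0.009),
            Kernel("T", (0.30, 0.20, -0.15), 0.550, 0.050),
        ])

    def scaled(self, factor: float) -> "BeatShapeParams":
        return BeatShapeParams([replace(k, vec=tuple(factor * v for v in k.vec))
                                for k in self.kernels])

    def get(self, name: str) -> Kernel:
        for k in self.kernels:
            if k.name == name:
                return k
        raise KeyError(name)

    def without_p(self) -> "BeatShapeParams":
        return BeatShapeParams([k for k in self.kernels if k.name != "P"])


def _rotate_frontal(vec: tuple[float, float, float], theta: float) -> tuple[float, float, float]:
    x, y, z = vec
    c, s = np.cos(theta), np.sin(theta)
    return (c * x - s * y, s * x + c * y, z)


def apply_diagnosis(params: BeatShapeParams, label: DiagnosisLabel) -> BeatShapeParams:
    """Perturb beat kernels according to the diagnosis class."""
    ks = {k.name: k for k in copy.deepcopy(params.kernels)}
    if label is DiagnosisLabel.NORMAL:
        pass
    elif label is DiagnosisLabel.ST_ELEVATION:
        ks["ST"] = Kernel("ST", (0.06, 0.02, -0.17), 0.410, 0.045)
    elif label is DiagnosisLabel.ST_DEPRESSION:
        ks["ST"] = Kernel("ST", (-0.04, -0.015, 0.11), 0.410, 0.045)
    elif label is DiagnosisLabel.OLD_MI:
        # lost initial anterior forces: QS morphology in the anterior leads
        ks["R"] = replace(ks["R"], vec=tuple(0.2 * v for v in ks["R"].vec))
        ks["Q"] = replace(ks["Q"], vec=tuple(2.2 * v for v in ks["Q"].vec))
        ks["S"] = replace(ks["S"], vec=tuple(1.5 * v for v in ks["S"].vec))
    elif label is DiagnosisLabel.CLBBB:
        for name in ("Q", "R", "S"):
            ks[name] = replace(ks[name], sigma=1.9 * ks[name].sigma)
        ks["Q"] = replace(ks["Q"], vec=tuple(0.1 * v for v in ks["Q"].vec))
        ks["QRSterm"] = Kernel("QRSterm", (0.55, 0.25, 0.40), 0.365, 0.022)
    elif label is DiagnosisLabel.CRBBB_RBBB:
        for name in ("R", "S"):
            ks[name] = replace(ks[name], sigma=1.3 * ks[name].sigma)
        ks["QRSterm"] = Kernel("QRSterm", (-0.25, -0.05, -0.55), 0.360, 0.018)
    elif label is DiagnosisLabel.LAH:
        for name in ("Q", "R", "S"):
            ks[name] = replace(ks[name], vec=_rotate_frontal(ks[name].vec, -0.9))
    order = ["P", "Q", "R", "S", "QRSterm", "ST", "T"]
    return BeatShapeParams([ks[n] for n in order if n in ks])


def _jitter_params(params: BeatShapeParams, rng: np.random.Generator) -> BeatShapeParams:
    """Subject-level biological variability around the template."""
    out = []
    theta = rng.normal(0.0, 0.12)
    for k in params.kernels:
        scale = float(np.clip(1.0 + 0.18 * rng.normal(), 0.65, 1.35))
        wid = float(np.clip(1.0 + 0.10 * rng.normal(), 0.85, 1.15))
        vec = _rotate_frontal(tuple(scale * v for v in k.vec), theta)
        out.append(Kernel(k.name, vec, k.mu, k.sigma * wid))
    return BeatShapeParams(out)


# ---------------------------------------------------------------------------
# Lead fields
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeadFieldMatrix:
    """12x3 projection weights mapping the dipole onto the 12 leads."""

    posture: Posture
    rows: np.ndarray  # (12, 3) aligned with LEAD_NAMES

    def __post_init__(self) -> None:
        object.__setattr__(self, "rows", np.asarray(self.rows, dtype=float))
        if self.rows.shape != (12, 3):
            raise ValueError("lead field must be 12x3")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("lead field entries must be finite")

    def row(self, lead: str) -> np.ndarray:
        return self.rows[LEAD_NAMES.index(lead)]

    @classmethod
    def from_transform(cls, matrix: TransformMatrix,
                       posture: Posture = Posture.SUPINE) -> "LeadFieldMatrix":
        full = matrix.full_rows()
        return cls(posture, np.vstack([full[lead] for lead in LEAD_NAMES]))

    @classmethod
    def from_selection(cls, rule: dict[str, TransformMatrix],
                       default: TransformMatrix,
                       posture: Posture = Posture.SUPINE) -> "LeadFieldMatrix":
        """Composite field: per-lead rows drawn from different transforms."""
        base = default.full_rows()
        for lead, m in rule.items():
            base[lead] = m.full_rows()[lead]
        return cls(posture, np.vstack([base[lead] for lead in LEAD_NAMES]))


def default_supine_field() -> LeadFieldMatrix:
    """Classic dipole lead vectors (Dower geometry) for the supine 12-lead set."""
    return LeadFieldMatrix.from_transform(DOWER, Posture.SUPINE)


def default_prone_field() -> LeadFieldMatrix:
    """Stylised prone lead field encoding the mirrored back-electrode geometry.

    Standard V1 pairs inversely with prone V4 (and vice versa), standard V2
    inversely with prone V2; prone V3/V5 sit midway between their
    neighbours; prone V6 keeps the standard V6 site; limb leads are
    posture-invariant.
    """
    sup = default_supine_field()
    rows = sup.rows.copy()
    idx = {lead: i for i, lead in enumerate(LEAD_NAMES)}
    rows[idx["V1"]] = -sup.row("V4")
    rows[idx["V2"]] = -sup.row("V2")
    rows[idx["V4"]] = -sup.row("V1")
    rows[idx["V6"]] = sup.row("V6")
    rows[idx["V3"]] = (rows[idx["V2"]] + rows[idx["V4"]]) / 2.0
    rows[idx["V5"]] = (rows[idx["V4"]] + rows[idx["V6"]]) / 2.0
    return LeadFieldMatrix(Posture.PRONE, rows)


# ---------------------------------------------------------------------------
# Simulation primitives
# ---------------------------------------------------------------------------

def simulate_vcg(params: BeatShapeParams, fs: float, n_beats: int,
                 seed: int = 0, rr_s: float = 1.0,
                 duration_s: float | None = None,
                 subject_id: str = "") -> VCGRecord:
    """Periodic dipole trajectory with P, QRS and T loop components.

    Each beat is the same kernel sum evaluated on a beat-local time grid;
    kernels decay to numerical zero at beat boundaries, so every per-beat
    loop closes.  Deterministic given (params, fs, n_beats, rr_s).
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rr = int(round(rr_s * fs))
    n = int(round(duration_s * fs)) if duration_s is not None else rr * n_beats
    t_local = np.arange(rr) / fs
    template = np.zeros((3, rr))
    for k in params.kernels:
        template += k.evaluate(t_local)
    xyz = np.zeros((3, n))
    for b in range(n_beats):
        start = b * rr
        stop = min(n, start + rr)
        xyz[:, start:stop] += template[:, : stop - start]
    return VCGRecord(xyz, fs=fs, subject_id=subject_id)


def project_leads(vcg: VCGRecord, fld: LeadFieldMatrix, noise_sd: float = 0.0,
                  seed: int = 0) -> ECGRecord:
    """Project a VCG through a lead field, adding white Gaussian noise."""
    sig = fld.rows @ vcg.xyz
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sig = sig + rng.normal(0.0, noise_sd, size=sig.shape)
    return ECGRecord(sig, LEAD_NAMES, vcg.fs, fld.posture, vcg.subject_id)


def truth_fiducials(params: BeatShapeParams, fs: float, n_beats: int,
                    rr_s: float = 1.0,
                    field: LeadFieldMatrix | None = None) -> list[BeatFiducials]:
    """Generator ground-truth fiducials, one per beat.

    Wave onsets/offsets are the 2.5-sigma points of the outermost kernel of
    each wave group (the conventional "visible departure from baseline"
    level, ~4% of the kernel peak); the T offset is the tangent-rule
    intercept computed analytically on the noise-free lead II template
    (for a Gaussian T this lands at mu + 2 sigma); the R peak is the
    largest absolute excursion of projected lead II inside the QRS window.
    """
    if field is None:
        field = default_supine_field()
    qrs = [k for k in params.kernels if k.name in QRS_KERNELS]
    p = next((k for k in params.kernels if k.name == "P"), None)
    t = next(k for k in params.kernels if k.name == "T")
    qrs_on_s = min(k.mu - 2.5 * k.sigma for k in qrs)
    qrs_off_s = max(k.mu + 2.5 * k.sigma for k in qrs)

    rr = int(round(rr_s * fs))
    t_local = np.arange(rr) / fs
    lead2 = field.row("II") @ sum(k.evaluate(t_local) for k in params.kernels)
    a, b = int(round(qrs_on_s * fs)), int(round(qrs_off_s * fs))
    r_local = a + int(np.argmax(np.abs(lead2[a:b])))

    # tangent-rule T offset on the noise-free template
    t_peak_i = int(round(t.mu * fs))
    tail = lead2[t_peak_i:]
    d = np.gradient(tail)
    sign = 1.0 if lead2[t_peak_i] >= 0 else -1.0
    k_steep = int(np.argmin(sign * d[: int(round(4 * t.sigma * fs))]))
    slope = d[k_steep]
    if abs(slope) > 1e-12:
        cross = k_steep + (0.0 - tail[k_steep]) / slope
    else:  # pragma: no cover - degenerate flat T
        cross = 2 * t.sigma * fs
    t_off_s = (t_peak_i + float(np.clip(cross, k_steep + 1, tail.size - 1))) / fs

    out = []
    for beat in range(n_beats):
        s0 = beat * rr
        if p is not None:
            p_on = s0 + int(round((p.mu - 2.5 * p.sigma) * fs))
            present = True
        else:
            p_on = s0 + int(round(qrs_on_s * fs)) - int(round(0.12 * fs))
            present = False
        out.append(BeatFiducials(
            p_onset=p_on,
            qrs_onset=s0 + int(round(qrs_on_s * fs)),
            r_peak=s0 + r_local,
            qrs_offset=s0 + int(round(qrs_off_s * fs)),
            t_offset=s0 + int(round(t_off_s * fs)),
            p_present=present,
        ))
    return out


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------

#: Development-cohort diagnosis mix (counts over 70 participants).
DEFAULT_CLASS_MIX: dict[DiagnosisLabel, float] = {
    DiagnosisLabel.NORMAL: 24 / 70,
    DiagnosisLabel.ST_ELEVATION: 7 / 70,
    DiagnosisLabel.OLD_MI: 8 / 70,
    DiagnosisLabel.ST_DEPRESSION: 11 / 70,
    DiagnosisLabel.CLBBB: 4 / 70,
    DiagnosisLabel.CRBBB_RBBB: 11 / 70,
    DiagnosisLabel.LAH: 5 / 70,
}

#: Truncated-normal covariate sampling rules: (mean, sd, low, high).
DEFAULT_COVARIATE_DISTRIBUTIONS: dict[str, tuple[float, float, float, float]] = {
    "age": (58.0, 16.0, 18.0, 90.0),
    "height": (168.0, 8.0, 145.0, 195.0),
    "weight": (67.0, 12.0, 40.0, 110.0),
    "chest": (90.3, 6.0, 70.0, 120.0),
    "waist": (86.4, 9.0, 60.0, 125.0),
}

DEFAULT_MALE_FRACTION = 41 / 70


@dataclass
class SyntheticCohortConfig:
    """Study-condition defaults: 70 subjects, 590 prone cycles, 500 Hz."""

    n_subjects: int = 70
    total_beats: int = 590
    fs: float = 500.0
    duration_s: float = 10.0
    noise_sd: float = 0.02
    class_mix: dict[DiagnosisLabel, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    covariate_distributions: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_DISTRIBUTIONS))
    male_fraction: float = DEFAULT_MALE_FRACTION
    seed: int = 0
    supine_field: LeadFieldMatrix | None = None
    prone_field: LeadFieldMatrix | None = None

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ConfigError("n_subjects must be >= 1")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-6:
            raise ConfigError(f"class_mix proportions must sum to 1, got {total}")


@dataclass
class SubjectData:
    """One simulated participant: paired-posture ECGs + shared VCG."""

    subject_id: str
    prone: ECGRecord
    supine: ECGRecord
    vcg: VCGRecord
    covariates: SubjectCovariates
    label: DiagnosisLabel
    fiducials: list[BeatFiducials]   # generator ground truth, shared time base
    params: BeatShapeParams

    @property
    def n_beats(self) -> int:
        return len(self.fiducials)


@dataclass
class CohortDataset:
    subjects: list[SubjectData]
    config: SyntheticCohortConfig

    def __iter__(self):
        return iter(self.subjects)

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def n_prone_cycles(self) -> int:
        return sum(s.n_beats for s in self.subjects)

    def subject_ids(self) -> list[str]:
        return [s.subject_id for s in self.subjects]


def _assign_labels(mix: dict[DiagnosisLabel, float], n: int,
                   rng: np.random.Generator) -> list[DiagnosisLabel]:
    """Largest-remainder apportionment of class counts, then shuffled."""
    labels = list(mix)
    raw = np.array([mix[lab] * n for lab in labels])
    counts = np.floor(raw).astype(int)
    rem = raw - counts
    for i in np.argsort(-rem)[: n - counts.sum()]:
        counts[i] += 1
    out: list[DiagnosisLabel] = []
    for lab, c in zip(labels, counts):
        out.extend([lab] * int(c))
    rng.shuffle(out)
    return out


def _beats_allocation(n_subjects: int, total: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Per-subject beat counts drawn from {7..10}, adjusted to sum to total."""
    beats = rng.integers(7, 11, size=n_subjects)
    lo, hi = 5, 12
    while beats.sum() != total:
        i = int(rng.integers(n_subjects))
        if beats.sum() > total and beats[i] > lo:
            beats[i] -= 1
        elif beats.sum() < total and beats[i] < hi:
            beats[i] += 1
    return beats


def _sample_covariates(dists, male_fraction: float,
                       rng: np.random.Generator) -> SubjectCovariates:
    vals = {}
    for name, (mean, sd, lo, hi) in dists.items():
        vals[name] = float(np.clip(rng.normal(mean, sd), lo, hi))
    return SubjectCovariates(male=int(rng.random() < male_fraction), **vals)


def simulate_cohort(config: SyntheticCohortConfig) -> CohortDataset:
    """Simulate the paired prone/supine cohort.

    Each subject gets one dipole trajectory (posture-invariant by
    construction) projected through the supine and prone lead fields; with
    ``noise_sd=0`` every generated lead is an exact linear function of
    (X, Y, Z), the recovery oracle for the regression approaches.
    """
    rng = np.random.default_rng(config.seed)
    sup_field = config.supine_field or default_supine_field()
    pro_field = config.prone_field or default_prone_field()
    labels = _assign_labels(config.class_mix, config.n_subjects, rng)
    beats = _beats_allocation(config.n_subjects, config.total_beats, rng)

    subjects = []
    for i in range(config.n_subjects):
        sid = f"S{i + 1:03d}"
        cov = _sample_covariates(config.covariate_distributions,
                                 config.male_fraction, rng)
        params = apply_diagnosis(_jitter_params(BeatShapeParams.default(), rng),
                                 labels[i])
        n_beats = int(beats[i])
        rr_s = config.duration_s / n_beats
        vcg = simulate_vcg(params, config.fs, n_beats, rr_s=rr_s,
                           duration_s=config.duration_s, subject_id=sid)
        noise_seeds = rng.integers(0, 2**31 - 1, size=2)
        prone = project_leads(vcg, pro_field, config.noise_sd, int(noise_seeds[0]))
        supine = project_leads(vcg, sup_field, config.noise_sd, int(noise_seeds[1]))
        fids = truth_fiducials(params, config.fs, n_beats, rr_s=rr_s,
                               field=sup_field)
        subjects.append(SubjectData(sid, prone, supine, vcg, cov,
                                    labels[i], fids, params))
    return CohortDataset(subjects, config)
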