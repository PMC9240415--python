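"""Synthetic cohorts with known ground truth.

Generates every input class the pipeline consumes — a topic-structured
corpus and LSA space, discourse transcripts for a control and a patient
group, seven orthogonal cognitive component scores, and stacks of synthetic
lesion images — so each analysis stage can be exercised end-to-end against
a planted truth.

Transcripts are built by a *topic-drift* process: each content token is
drawn from the task's on-topic lexicon with probability (1 - d) and from a
shared off-topic lexicon with probability d, where d is the participant's
drift rate. Every lexicon is partitioned into sub-topics (aspects of the
scene or procedure); each participant holds a Dirichlet-distributed
preference over sub-topics, so different speakers emphasize different
aspects and even fully on-topic responses disperse around the group
prototype — without this, every control response would score ~1.0. Patients
drift more than controls and concentrate on fewer sub-topics; drift rates
and Dirichlet concentrations are calibrated so that scored group means land
near the published group descriptive statistics (control ~0.84-0.91,
patient ~0.61-0.74 across tasks). Lesions are contiguous random blobs grown on a 3D grid with sizes
drawn from a lognormal calibrated to the reference cohort (mean 15497,
SD 11188, range 175-41379 voxels, truncated to half the grid volume at
desk scale); behaviour declines linearly with the lesioned fraction of a
planted critical region.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .coherence import TASKS, ResponseRecord
from .lesion_mapping import LesionDataset, fwhm_to_sigma
from .semantic_space import SemanticSpace, build_space
from .stoplist import DEFAULT_STOPLIST

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "TASK_LEXICONS",
    "OFF_TOPIC_LEXICON",
    "make_corpus_and_space",
    "make_transcripts",
    "make_component_scores",
    "make_lesion_cohort",
]

TASK_LEXICONS: dict[str, tuple[str, ...]] = {
    "picture_description": (
        "boy", "girl", "mother", "cookie", "cookies", "jar", "stool", "sink",
        "overflowing", "dishes", "plate", "kitchen", "window", "curtain",
        "reaching", "stealing", "cupboard", "tap", "drying", "falling",
        "wobbling", "washing", "counter", "apron", "lid",
    ),
    "storytelling": (
        "dinner", "party", "guests", "host", "hostess", "cooking", "burnt",
        "wine", "glasses", "evening", "friends", "doorbell", "dessert",
        "salad", "oven", "smoke", "laughing", "serving", "napkin", "candles",
        "roast", "table", "invitation", "toast", "chatting",
    ),
    "procedural": (
        "tea", "kettle", "water", "boil", "boiling", "cup", "teabag", "milk",
        "sugar", "spoon", "stir", "pour", "mug", "brew", "steep", "minutes",
        "teapot", "strainer", "leaves", "drink", "saucer", "fill", "switch",
        "wait", "squeeze",
    ),
}

OFF_TOPIC_LEXICON: tuple[str, ...] = (
    "weather", "holiday", "football", "garden", "train", "mountain", "river",
    "shopping", "money", "church", "doctor", "hospital", "school", "teacher",
    "music", "dancing", "road", "dog", "cat", "newspaper", "television",
    "bus", "seaside", "rain", "war",
)

# a few function words woven into transcripts for realism; scoring strips them
_FILLERS = ("the", "and", "a", "is", "it", "um", "to", "of")


@dataclass
class GeneratorConfig:
    """Tunable study conditions for all generators (defaults emulate the
    reference cohort: 20 controls, 46 patients)."""

    seed: int = 0
    n_controls: int = 20
    n_patients: int = 46
    task_lexicons: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(TASK_LEXICONS))
    off_topic_lexicon: tuple[str, ...] = OFF_TOPIC_LEXICON
    # topic-drift calibration (probability a content token is off-topic);
    # per-participant rates are drawn around these group means
    control_drift_mean: float = 0.05
    control_drift_sd: float = 0.03
    patient_drift_mean: float = 0.32
    patient_drift_sd: float = 0.22
    # the procedural task elicits the most focused responses in both groups
    task_drift_scale: dict[str, float] = field(default_factory=lambda: {
        "picture_description": 1.1, "storytelling": 1.0, "procedural": 0.55})
    # sub-topic structure: each lexicon splits into this many aspects, and a
    # participant's emphasis over aspects is Dirichlet(concentration); the
    # focused procedural task gets a higher effective concentration
    subtopics: int = 5
    control_concentration: float = 2.5
    patient_concentration: float = 1.0
    task_focus: dict[str, float] = field(default_factory=lambda: {
        "picture_description": 0.85, "storytelling": 1.0, "procedural": 3.0})
    control_length_mean: int = 45
    patient_length_mean: int = 18
    empty_response_fraction: float = 0.0
    # component -> coherence generation (reference coefficient values)
    coefficients: dict[str, float] = field(default_factory=lambda: {
        "phonological_production": 0.132,
        "semantic_processing": 0.101,
        "verbal_fluency": 0.08,
    })
    coherence_intercept: float = 0.67
    noise_sd: float = 0.05
    # lesion cohort
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 2.0
    lesion_size_mean: float = 15497.0
    lesion_size_sd: float = 11188.0
    lesion_size_range: tuple[int, int] = (175, 41379)
    critical_region: tuple[slice, slice, slice] = (
        slice(5, 10), slice(18, 23), slice(15, 20))
    # fraction of lesions whose growth seed falls inside the critical
    # region, emulating the clustering of real stroke lesions within one
    # vascular territory; the rest seed uniformly over the grid
    lesion_seed_region_fraction: float = 0.0
    # (mean, sd) voxel count for region-seeded lesions; None = draw from the
    # same size distribution as background lesions
    region_lesion_size: tuple[float, float] | None = None
    lesion_effect: float = 0.45
    lesion_noise_sd: float = 0.05
    behaviour_baseline: float = 0.85
    age_mean: float = 63.21
    age_sd: float = 11.93
    age_range: tuple[float, float] = (44.0, 87.0)
    months_mean: float = 69.43
    months_sd: float = 48.86
    months_range: tuple[float, float] = (16.0, 280.0)
    fwhm_mm: float = 8.0

    @classmethod
    def lesion_recovery(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Planted-effect recovery conditions: a 9x9x9 critical region,
        half the lesions seeded inside it at region scale (compact
        territory-like blobs), larger background lesions elsewhere, strong
        effect and low noise."""
        kw = dict(
            seed=seed,
            lesion_size_mean=3000.0, lesion_size_sd=2000.0,
            lesion_size_range=(200, 8000),
            critical_region=(slice(5, 14), slice(15, 24), slice(13, 22)),
            lesion_seed_region_fraction=0.5, region_lesion_size=(600.0, 200.0),
            lesion_effect=0.8, lesion_noise_sd=0.03,
        )
        kw.update(overrides)
        return cls(**kw)

    @classmethod
    def lesion_calibration(cls, seed: int = 0, **overrides) -> "GeneratorConfig":
        """Null-calibration conditions: modest lesion sizes (fast to grow
        and map) and no planted effect; pass ``effect=0`` when generating."""
        kw = dict(
            seed=seed,
            lesion_size_mean=2000.0, lesion_size_sd=1500.0,
            lesion_size_range=(175, 8000),
        )
        kw.update(overrides)
        return cls(**kw)

    def __post_init__(self) -> None:
        pools = [set(p) for p in self.task_lexicons.values()]
        pools.append(set(self.off_topic_lexicon))
        for i, a in enumerate(pools):
            for b in pools[i + 1:]:
                if a & b:
                    raise ValueError(f"lexicon pools overlap: {sorted(a & b)}")
            if a & DEFAULT_STOPLIST:
                raise ValueError(
                    f"pool words collide with stoplist: {sorted(a & DEFAULT_STOPLIST)}")


@dataclass
class GroundTruth:
    """Planted truth serialized alongside every generated cohort."""

    drift_rates: dict[str, float] = field(default_factory=dict)
    coefficients: dict[str, float] = field(default_factory=dict)
    critical_region_mask: np.ndarray | None = None
    critical_load: dict[str, float] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "drift_rates": self.drift_rates,
            "coefficients": self.coefficients,
            "critical_region_voxels": (
                np.argwhere(self.critical_region_mask).tolist()
                if self.critical_region_mask is not None else None),
            "critical_load": self.critical_load,
        }
        Path(path).write_text(json.dumps(payload, indent=1), encoding="utf-8")


def _partition(pool, m: int) -> list[list[str]]:
    pool = list(pool)
    return [pool[i::m] for i in range(m)]


def make_corpus_and_space(
    config: GeneratorConfig,
    n_docs_per_subtopic: int = 8,
    doc_length: int = 30,
    k: int = 24,
    leakage: float = 0.15,
) -> tuple[list[list[str]], SemanticSpace]:
    """Build a topic-blocked corpus and its LSA space.

    Each topic pool (three task lexicons plus the off-topic lexicon) is
    split into ``config.subtopics`` sub-topics; every sub-topic contributes
    ``n_docs_per_subtopic`` documents drawn mostly from that sub-topic with
    a small ``leakage`` fraction from sibling sub-topics of the same pool.
    Words within a sub-topic therefore co-occur tightly, words within a pool
    loosely, and words across pools essentially never — giving the graded
    cosine structure the drift process needs.
    """
    rng = np.random.default_rng(config.seed)
    pools = list(config.task_lexicons.values()) + [config.off_topic_lexicon]
    docs: list[list[str]] = []
    for pool in pools:
        subs = _partition(pool, config.subtopics)
        for si, sub in enumerate(subs):
            siblings = [w for j, s in enumerate(subs) if j != si for w in s]
            for _ in range(n_docs_per_subtopic):
                doc = []
                for _ in range(doc_length):
                    src = siblings if rng.random() < leakage else sub
                    doc.append(str(rng.choice(src)))
                docs.append(doc)
    order = rng.permutation(len(docs))
    docs = [docs[i] for i in order]
    space = build_space(docs, k=k, weighting="log-entropy", min_count=2,
                        provenance=f"synthetic topic corpus, seed={config.seed}")
    return docs, space


def _draw_drift(rng: np.random.Generator, mean: float, sd: float) -> float:
    return float(np.clip(rng.normal(mean, sd), 0.0, 0.95))


def _make_response(rng: np.random.Generator, on_subs, off_subs,
                   on_weights, off_weights, drift: float, length: int) -> str:
    words = []
    for _ in range(max(1, length)):
        if rng.random() < drift:
            sub = off_subs[rng.choice(len(off_subs), p=off_weights)]
        else:
            sub = on_subs[rng.choice(len(on_subs), p=on_weights)]
        words.append(str(rng.choice(sub)))
        if rng.random() < 0.4:
            words.append(str(rng.choice(_FILLERS)))
    return " ".join(words)


def make_transcripts(
    config: GeneratorConfig,
    out_dir: str | Path | None = None,
) -> tuple[list[ResponseRecord], GroundTruth]:
    """Generate control and patient transcripts for all three tasks.

    Each participant gets a single drift rate (patients drifting more, with
    greater spread); per-task drift is that rate times the task's scale
    factor. Response lengths follow a Poisson around the group mean. With
    ``empty_response_fraction`` > 0, that fraction of patients gets one empty
    response to exercise missing-task handling.

    If ``out_dir`` is given, writes one text file per response plus a
    ``manifest.tsv`` (participant_id, group, task, file) and
    ``ground_truth.json``.
    """
    rng = np.random.default_rng(config.seed + 1)
    records: list[ResponseRecord] = []
    truth = GroundTruth(coefficients=dict(config.coefficients))

    roster = [(f"C{i + 1:02d}", "control") for i in range(config.n_controls)]
    roster += [(f"P{i + 1:02d}", "patient") for i in range(config.n_patients)]
    empty_ids = set()
    if config.empty_response_fraction > 0:
        patients = [pid for pid, g in roster if g == "patient"]
        n_empty = int(round(config.empty_response_fraction * len(patients)))
        empty_ids = set(rng.choice(patients, size=n_empty, replace=False))

    on_subs = {t: _partition(config.task_lexicons[t], config.subtopics)
               for t in TASKS}
    off_subs = _partition(config.off_topic_lexicon, config.subtopics)

    for pid, group in roster:
        if group == "control":
            drift = _draw_drift(rng, config.control_drift_mean, config.control_drift_sd)
            length_mean = config.control_length_mean
            conc = config.control_concentration
        else:
            drift = _draw_drift(rng, config.patient_drift_mean, config.patient_drift_sd)
            length_mean = config.patient_length_mean
            conc = config.patient_concentration
        truth.drift_rates[pid] = drift
        empty_task = rng.choice(TASKS) if pid in empty_ids else None
        for task in TASKS:
            if task == empty_task:
                text = ""
            else:
                d = min(0.95, drift * config.task_drift_scale[task])
                alpha = conc * config.task_focus[task]
                w_on = rng.dirichlet([alpha] * config.subtopics)
                w_off = rng.dirichlet([alpha] * config.subtopics)
                length = max(3, int(rng.poisson(length_mean)))
                text = _make_response(rng, on_subs[task], off_subs,
                                      w_on, w_off, d, length)
            records.append(ResponseRecord(pid, group, task, text))

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        rows = []
        for r in records:
            fname = f"{r.participant_id}_{r.task}.txt"
            (out_dir / fname).write_text(r.raw_text, encoding="utf-8")
            rows.append({"participant_id": r.participant_id, "group": r.group,
                         "task": r.task, "file": fname})
        pd.DataFrame(rows).to_csv(out_dir / "manifest.tsv", sep="\t", index=False)
        truth.to_json(out_dir / "ground_truth.json")
    return records, truth


_COMPONENTS = (
    "phonological_production", "semantic_processing", "phonological_recognition",
    "verbal_fluency", "verbal_quality", "motor_speech", "executive_functions",
)


def make_component_scores(
    config: GeneratorConfig,
    composite: pd.Series | np.ndarray | None = None,
    mode: str = "forward",
) -> tuple[pd.DataFrame, np.ndarray, GroundTruth]:
    """Seven orthogonalized standard-normal component columns per patient.

    ``mode="forward"``: coherence is regenerated as X @ B + intercept + noise
    from the planted coefficient vector, giving regression-recovery tests an
    exact known truth (returned as the second element).
    ``mode="null"``: components are independent of the supplied (or
    standard-normal) coherence vector.
    """
    if config.noise_sd < 0:
        raise ValueError("noise SD must be >= 0")
    n = config.n_patients
    if n < 10:
        raise ValueError("need at least 10 patients")
    rng = np.random.default_rng(config.seed + 2)
    raw = rng.normal(size=(n, len(_COMPONENTS)))
    raw -= raw.mean(axis=0)
    q, _ = np.linalg.qr(raw)           # orthogonal, still zero-mean columns
    comps = q / q.std(axis=0, ddof=0)  # exact pairwise correlation 0
    df = pd.DataFrame(comps, columns=_COMPONENTS)
    df.insert(0, "participant_id", [f"P{i + 1:02d}" for i in range(n)])

    truth = GroundTruth(coefficients=dict(config.coefficients))
    if mode == "forward":
        y = np.full(n, config.coherence_intercept)
        for name, b in config.coefficients.items():
            y = y + b * df[name].to_numpy()
        y = y + rng.normal(0, config.noise_sd, size=n)
    elif mode == "null":
        if composite is None:
            y = rng.normal(0.67, 0.15, size=n)
        else:
            y = np.asarray(composite, dtype=float)
        truth.coefficients = {}
    else:
        raise ValueError("mode must be 'forward' or 'null'")
    return df, y, truth


def _grow_blob(rng: np.random.Generator, grid: tuple[int, int, int],
               size: int, seed_voxel: tuple[int, int, int] | None = None
               ) -> np.ndarray:
    """Grow a contiguous random blob of ~``size`` voxels by stochastic
    frontier accretion from a seed voxel (random if not given)."""
    blob = np.zeros(grid, dtype=bool)
    seed = seed_voxel or tuple(rng.integers(0, s) for s in grid)
    blob[seed] = True
    structure = ndimage.generate_binary_structure(3, 1)
    current = 1
    while current < size:
        frontier = ndimage.binary_dilation(blob, structure) & ~blob
        cand = np.argwhere(frontier)
        if len(cand) == 0:
            break
        take = min(len(cand), size - current,
                   max(1, int(len(cand) * rng.uniform(0.5, 0.9))))
        chosen = cand[rng.choice(len(cand), size=take, replace=False)]
        blob[tuple(chosen.T)] = True
        current += take
    return blob


def make_lesion_cohort(
    config: GeneratorConfig,
    effect: float | None = None,
    continuous: bool = True,
) -> tuple[LesionDataset, GroundTruth]:
    """Simulate a lesion cohort with a planted critical region.

    Per patient, a contiguous random blob is grown with size drawn from a
    lognormal calibrated to the reference cohort's lesion-size statistics,
    truncated to the configured range and to half the grid volume.
    Behaviour = baseline - effect * (fraction of the critical region
    lesioned) + Gaussian noise, clipped to [0, 1]. ``effect=0`` yields a
    null cohort for calibration experiments. With ``continuous=True`` the
    images are Gaussian-smoothed versions of the binary masks (for VBCM);
    otherwise the binary masks themselves (for SVR-LSM).

    Covariates (age, months post-onset) are drawn from the reference
    demographic ranges, independent of behaviour.
    """
    rng = np.random.default_rng(config.seed + 3)
    if effect is None:
        effect = config.lesion_effect
    grid = config.grid_shape
    n_grid = int(np.prod(grid))
    lo, hi = config.lesion_size_range
    hi = min(hi, n_grid // 2)
    if lo > hi:
        raise ValueError("lesion size range empty after grid truncation")

    region = np.zeros(grid, dtype=bool)
    region[config.critical_region] = True
    if not region.any():
        raise ValueError("critical region outside grid")
    mean, sd = config.lesion_size_mean, config.lesion_size_sd
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2

    n = config.n_patients
    binary = np.zeros((n, *grid), dtype=float)
    load = np.zeros(n)
    region_voxels = np.argwhere(region)
    for i in range(n):
        size = int(np.clip(rng.lognormal(mu, np.sqrt(sigma2)), lo, hi))
        seed_voxel = None
        if rng.random() < config.lesion_seed_region_fraction:
            seed_voxel = tuple(region_voxels[rng.integers(len(region_voxels))])
            if config.region_lesion_size is not None:
                rm, rs = config.region_lesion_size
                size = int(np.clip(rng.normal(rm, rs), lo, hi))
        blob = _grow_blob(rng, grid, size, seed_voxel)
        binary[i] = blob
        load[i] = blob[region].sum() / region.sum()

    typical = np.exp(mu)
    if region.sum() > typical:
        import warnings
        warnings.warn("critical region larger than the typical lesion; "
                      "the planted effect will rarely be expressed", stacklevel=2)

    behaviour = np.clip(
        config.behaviour_baseline - effect * load
        + rng.normal(0, config.lesion_noise_sd, size=n), 0.0, 1.0)

    # analysis mask = union of the binary lesions; smoothing tails outside
    # any lesion carry no information and would only inflate the mask
    mask = binary.any(axis=0)
    if continuous:
        sig = fwhm_to_sigma(config.fwhm_mm) / config.voxel_size
        images = np.stack([
            np.clip(ndimage.gaussian_filter(b, sigma=sig), 0.0, 1.0)
            for b in binary])
    else:
        images = binary

    age = np.clip(rng.normal(config.age_mean, config.age_sd, size=n),
                  *config.age_range)
    months = np.clip(rng.normal(config.months_mean, config.months_sd, size=n),
                     *config.months_range)
    covs = pd.DataFrame({"age": age, "months_post_onset": months})

    ds = LesionDataset(images=images, behaviour=behaviour, covariates=covs,
                       mask=mask, voxel_size=config.voxel_size)
    truth = GroundTruth(critical_region_mask=region,
                        critical_load={f"P{i + 1:02d}": float(load[i])
                                       for i in range(n)})
    return ds, truth
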