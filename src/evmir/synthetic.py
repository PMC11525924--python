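"""Synthetic case/control miRNA-microarray cohorts with planted ground truth.

The generator emulates the structure of a urinary extracellular-vesicle
miRNA profiling study: a platform of ~2565 probe species, a core subset
detected in every subject, a per-subject detection count with median around
1500, log-normal baseline fluorescence, and a cancer group in which a known
set of species is up- or down-regulated by a fixed log2 fold change.
It also builds a toy pathway database (gene sets over a fixed background
universe) and a miRNA->target-gene map in which the targets of designated
signal miRNAs over-represent planted pathways, so the enrichment stage has
a testable positive control.

Everything is deterministic under the spec seed: sub-streams are spawned
from a single ``numpy.random.SeedSequence``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import InvalidSpecError
from .matrix import IntensityMatrix, CohortLabels

DEFAULT_STAGE_FRACTIONS = {"I": 0.24, "II": 0.24, "III": 0.26, "IV": 0.26}


@dataclass
class CohortSpec:
    """Parameters of a synthetic case/control cohort.

    Defaults mirror the study design this simulator emulates: 2565 probe
    species of which 441 are detected in all subjects, ~1500 species
    detected per subject, 100 cancer (24 of them stage I) vs 100 noncancer
    subjects, and 48 up- / 6 down-regulated species at |log2 FC| = 1.5.

    ``baseline_mean``/``baseline_sd`` are the per-species baseline log2
    fluorescence distribution; ``noise_sd`` is per-observation log2 noise.
    ``plant_in_core`` restricts planted differential species to the
    always-detected core (a usable biomarker must be commonly measured);
    set False to plant anywhere. ``prevalence_beta_a`` is the alpha of the
    Beta prevalence distribution for non-core species (a modeling stand-in,
    exposed as a knob rather than asserted as faithful).
    """

    n_cancer: int = 100
    n_noncancer: int = 100
    n_species: int = 2565
    core_fraction: float = 441 / 2565
    target_median_detected: float = 1500.0
    baseline_mean: float = 6.0
    baseline_sd: float = 2.0
    noise_sd: float = 1.0
    n_up: int = 48
    n_down: int = 6
    effect_log2fc: float = 1.5
    stage_fractions: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_FRACTIONS))
    plant_in_core: bool = True
    prevalence_beta_a: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_cancer", "n_noncancer", "n_species"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be positive")
        if not (0.0 < self.core_fraction <= 1.0):
            raise InvalidSpecError("core_fraction must be in (0, 1]")
        if self.n_up < 0 or self.n_down < 0:
            raise InvalidSpecError("planted species counts must be nonnegative")
        if self.n_up + self.n_down > self.n_species:
            raise InvalidSpecError("n_up + n_down exceeds n_species")
        if self.baseline_sd <= 0 or self.noise_sd <= 0:
            raise InvalidSpecError("baseline_sd and noise_sd must be positive")
        if self.effect_log2fc < 0:
            raise InvalidSpecError("effect_log2fc must be nonnegative")
        total = sum(self.stage_fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidSpecError(f"stage_fractions must sum to 1, got {total}")
        n_core = round(self.core_fraction * self.n_species)
        if self.target_median_detected < n_core or self.target_median_detected > self.n_species:
            raise InvalidSpecError(
                "target_median_detected must lie between the core size and n_species"
            )


@dataclass
class SyntheticGroundTruth:
    """Planted structure of a synthetic cohort: which species carry an
    effect, its size in log2 units, and each species' detection prevalence."""

    planted_up_ids: list
    planted_down_ids: list
    effects: pd.Series            # delta_j, log2 units; 0 for null species
    prevalence: pd.Series         # pi_j in [0, 1]
    seed: int

    @property
    def planted_ids(self) -> list:
        return list(self.planted_up_ids) + list(self.planted_down_ids)


@dataclass
class SyntheticCohort:
    """A generated cohort: raw intensities + labels + ground truth."""

    matrix: IntensityMatrix       # state 'raw'
    labels: CohortLabels
    truth: SyntheticGroundTruth
    spec: CohortSpec


def _stage_assignment(spec: CohortSpec, rng: np.random.Generator) -> list:
    """Deterministic largest-remainder apportionment of stages, then shuffle."""
    names = sorted(spec.stage_fractions)
    fracs = np.array([spec.stage_fractions[s] for s in names])
    ideal = fracs * spec.n_cancer
    counts = np.floor(ideal).astype(int)
    rem = spec.n_cancer - counts.sum()
    order = np.argsort(-(ideal - counts), kind="stable")
    for i in order[:rem]:
        counts[i] += 1
    stages = [s for s, c in zip(names, counts) for _ in range(c)]
    rng.shuffle(stages)
    return stages


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Draw a cohort from the generative model.

    Model: per-species baseline mu_j ~ N(baseline_mean, baseline_sd) in
    log2 units; observed log2 intensity mu_j + delta_j*1[cancer] + eps with
    eps ~ N(0, noise_sd); raw fluorescence is 2**log2 where detected, 0
    elsewhere. Detection is per-species Bernoulli(pi_j) per subject with
    pi_j = 1 for the core subset; non-core prevalences are Beta draws
    rescaled so the expected detected-species count per subject equals
    ``target_median_detected``.
    """
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    (rng_core, rng_prev, rng_plant, rng_base, rng_noise,
     rng_detect, rng_stage) = (np.random.default_rng(s) for s in ss.spawn(7))

    p, n = spec.n_species, spec.n_cancer + spec.n_noncancer
    probe_ids = pd.Index([f"miR-{j:04d}" for j in range(1, p + 1)], name="probe_id")
    sample_ids = pd.Index(
        [f"CA-{i:04d}" for i in range(1, spec.n_cancer + 1)]
        + [f"NC-{i:04d}" for i in range(1, spec.n_noncancer + 1)],
        name="sample_id",
    )
    is_cancer = np.zeros(n, dtype=bool)
    is_cancer[: spec.n_cancer] = True

    # core subset: always detected
    n_core = round(spec.core_fraction * p)
    core_idx = np.sort(rng_core.choice(p, size=n_core, replace=False))
    is_core = np.zeros(p, dtype=bool)
    is_core[core_idx] = True

    # detection prevalence: Beta for non-core, rescaled to hit the target
    prevalence = np.ones(p)
    n_rest = p - n_core
    if n_rest > 0:
        mean_pi = (spec.target_median_detected - n_core) / n_rest
        a = spec.prevalence_beta_a
        b = a * (1.0 - mean_pi) / mean_pi
        pi = rng_prev.beta(a, b, size=n_rest)
        # rescale so the expected detected count per subject hits the target
        pi *= (spec.target_median_detected - n_core) / pi.sum()
        pi = np.clip(pi, 0.0, 1.0)
        prevalence[~is_core] = pi

    # planted effects
    pool = core_idx if (spec.plant_in_core and n_core >= spec.n_up + spec.n_down) \
        else np.arange(p)
    planted = rng_plant.choice(pool, size=spec.n_up + spec.n_down, replace=False)
    up_idx, down_idx = planted[: spec.n_up], planted[spec.n_up:]
    effects = np.zeros(p)
    effects[up_idx] = spec.effect_log2fc
    effects[down_idx] = -spec.effect_log2fc

    # log2 intensities and detection
    mu = rng_base.normal(spec.baseline_mean, spec.baseline_sd, size=p)
    log2_vals = (
        mu[:, None]
        + effects[:, None] * is_cancer[None, :]
        + rng_noise.normal(0.0, spec.noise_sd, size=(p, n))
    )
    detected = rng_detect.random((p, n)) < prevalence[:, None]
    raw = np.where(detected, np.exp2(log2_vals), 0.0)

    matrix = IntensityMatrix(
        values=pd.DataFrame(raw, index=probe_ids, columns=sample_ids),
        mask=pd.DataFrame(detected, index=probe_ids, columns=sample_ids),
        state="raw",
    )
    stages = _stage_assignment(spec, rng_stage) + ["NA"] * spec.n_noncancer
    labels = CohortLabels(pd.DataFrame(
        {"label": ["cancer"] * spec.n_cancer + ["noncancer"] * spec.n_noncancer,
         "stage": stages},
        index=sample_ids,
    ))
    truth = SyntheticGroundTruth(
        planted_up_ids=sorted(probe_ids[up_idx]),
        planted_down_ids=sorted(probe_ids[down_idx]),
        effects=pd.Series(effects, index=probe_ids, name="delta_log2"),
        prevalence=pd.Series(prevalence, index=probe_ids, name="prevalence"),
        seed=spec.seed,
    )
    return SyntheticCohort(matrix=matrix, labels=labels, truth=truth, spec=spec)


@dataclass
class PathwaySignalTruth:
    """Which pathways were planted as enriched and how the signal was wired."""

    planted_pathway_ids: list
    signal_mirna_ids: list
    planted_target_fraction: float
    seed: int


def generate_pathway_db(
    n_pathways: int = 338,
    n_background_genes: int = 8430,
    planted_enriched: int = 0,
    seed: int = 0,
    mirna_ids=None,
    n_mirnas: int = 100,
    signal_mirna_ids=None,
    targets_per_mirna: int = 30,
    planted_target_fraction: float = 0.6,
    min_pathway_size: int = 10,
    max_pathway_size: int = 200,
):
    """Build a toy gene-set database and a miRNA->target map.

    Pathway gene sets are uniform draws (log-normal sizes) from a fixed
    background universe of ``n_background_genes`` gene ids. Each miRNA gets
    ``targets_per_mirna`` target genes; for miRNAs in ``signal_mirna_ids``
    each target is drawn from the union of the ``planted_enriched`` planted
    pathways' genes with probability ``planted_target_fraction`` (uniform
    from the background otherwise), so those pathways are over-represented
    among signal-miRNA targets by a controlled margin.

    Returns ``(PathwayDB, TargetMap, PathwaySignalTruth)``.
    """
    from .enrichment import PathwayDB, TargetMap

    if planted_enriched > n_pathways:
        raise InvalidSpecError("planted_enriched exceeds n_pathways")
    if n_pathways <= 0 or n_background_genes <= 0:
        raise InvalidSpecError("n_pathways and n_background_genes must be positive")
    if not (0.0 <= planted_target_fraction < 1.0):
        raise InvalidSpecError("planted_target_fraction must be in [0, 1)")

    ss = np.random.SeedSequence(seed)
    rng_size, rng_genes, rng_plant, rng_targets = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    background = [f"G{g:05d}" for g in range(1, n_background_genes + 1)]
    bg_arr = np.array(background)

    sizes = np.clip(
        np.round(rng_size.lognormal(np.log(40.0), 0.6, size=n_pathways)).astype(int),
        min_pathway_size, min(max_pathway_size, n_background_genes),
    )
    pathways = {}
    for k in range(n_pathways):
        genes = rng_genes.choice(n_background_genes, size=sizes[k], replace=False)
        pathways[f"PATH-{k + 1:04d}"] = set(bg_arr[genes])
    # the background is defined as the union of pathway genes; park any
    # uncovered gene in a random pathway so the universe is exactly covered
    uncovered = sorted(set(background) - set().union(*pathways.values()))
    if uncovered:
        pids = sorted(pathways)
        for g, k in zip(uncovered,
                        rng_genes.integers(0, n_pathways, size=len(uncovered))):
            pathways[pids[k]].add(g)
    pathways = {pid: frozenset(genes) for pid, genes in pathways.items()}

    planted_pw = sorted(
        f"PATH-{k + 1:04d}"
        for k in rng_plant.choice(n_pathways, size=planted_enriched, replace=False)
    )
    planted_union = np.array(sorted(set().union(*(pathways[pid] for pid in planted_pw)))) \
        if planted_pw else np.array([], dtype=object)

    if mirna_ids is None:
        mirna_ids = [f"miR-{j:04d}" for j in range(1, n_mirnas + 1)]
    mirna_ids = list(mirna_ids)
    signal = set(signal_mirna_ids or [])

    targets = {}
    for mid in mirna_ids:
        if mid in signal and len(planted_union) > 0:
            from_planted = rng_targets.random(targets_per_mirna) < planted_target_fraction
            n_pl = int(from_planted.sum())
            picked = set(rng_targets.choice(planted_union, size=min(n_pl, len(planted_union)),
                                            replace=False))
            picked |= set(bg_arr[rng_targets.choice(n_background_genes,
                                                    size=targets_per_mirna - len(picked),
                                                    replace=False)])
        else:
            picked = set(bg_arr[rng_targets.choice(n_background_genes,
                                                   size=targets_per_mirna, replace=False)])
        targets[mid] = frozenset(picked)

    db = PathwayDB(pathways=pathways, background=frozenset(background))
    tmap = TargetMap(targets=targets)
    truth = PathwaySignalTruth(
        planted_pathway_ids=planted_pw,
        signal_mirna_ids=sorted(signal),
        planted_target_fraction=planted_target_fraction,
        seed=seed,
    )
    return db, tmap, truth


def ground_truth_to_dict(truth: SyntheticGroundTruth) -> dict:
    """JSON-serializable view of the ground truth."""
    return {
        "planted_up_ids": list(truth.planted_up_ids),
        "planted_down_ids": list(truth.planted_down_ids),
        "effects": {k: float(v) for k, v in truth.effects.items() if v != 0.0},
        "prevalence": {k: float(v) for k, v in truth.prevalence.items()},
        "seed": truth.seed,
    }
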