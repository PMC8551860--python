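"""Forward simulator of a backcross-derived NAM population.

The simulator reproduces the breeding and conservation design the fixation
statistics are built for: 25 wild donors crossed to one recurrent elite
parent, one backcross, three selfing generations by single-seed descent
(the genotyped BC1S3 plants), then five further seasons of plot propagation
— sow a plot from the previous season's harvested ears, optionally let
per-locus fitness skew survival (viability selection) or the choice of
harvested ears (harvest selection), and finally genotype a pooled DNA
sample of 12 seedlings with a tolerance-based allele caller.

Recombination follows the Haldane model: crossover counts per chromosome
are Poisson with mean L/100 (L in cM), positions uniform, no interference.
Batch gamete generation uses the equivalent Markov chain along the marker
skeleton, switching source haplotype between adjacent markers with
probability r = (1 - exp(-2d/100))/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .matrix import GenotypeMatrix, validate_genetic_map

__all__ = [
    "make_genetic_map",
    "Founders",
    "make_founders",
    "meiosis",
    "make_bc1s3_population",
    "SelectedLocus",
    "SelectionModel",
    "Season",
    "PropagationSchedule",
    "default_schedule",
    "propagate_line",
    "pool_and_call",
    "ExperimentConfig",
    "SimulationResult",
    "simulate_experiment",
]

# barley-like default: seven chromosomes named 1H..7H
_DEFAULT_CHROMS = ("1H", "2H", "3H", "4H", "5H", "6H", "7H")


def make_genetic_map(
    n_snps: int,
    chromosomes: tuple[str, ...] = _DEFAULT_CHROMS,
    length_cm: float = 150.0,
) -> pd.DataFrame:
    """Evenly spaced genetic map with ``n_snps`` markers over the chromosomes.

    Markers are distributed as evenly as possible across chromosomes and
    placed at regular cM intervals spanning ``length_cm`` per chromosome.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if not chromosomes:
        raise ValueError("need at least one chromosome")
    per = np.full(len(chromosomes), n_snps // len(chromosomes), dtype=int)
    per[: n_snps % len(chromosomes)] += 1
    rows = []
    for chrom, k in zip(chromosomes, per):
        if k == 0:
            continue
        pos = np.linspace(0.0, length_cm, k) if k > 1 else np.array([length_cm / 2.0])
        for i, cm in enumerate(pos):
            rows.append((f"{chrom}_{i + 1:05d}", chrom, float(cm)))
    return pd.DataFrame(rows, columns=["snp", "chrom", "cm"])


# ---------------------------------------------------------------------------
# map bookkeeping for gamete generation


def _haldane(d_cm: np.ndarray) -> np.ndarray:
    """Recombination fraction between markers d centiMorgans apart."""
    return 0.5 * (1.0 - np.exp(-np.asarray(d_cm, dtype=float) / 50.0))


@dataclass(frozen=True)
class _MapInfo:
    """Precomputed per-marker arrays used by the gamete generators."""

    cm: np.ndarray            # (S,) positions
    chrom_id: np.ndarray      # (S,) integer chromosome codes
    r_full: np.ndarray        # (S,) switch probabilities; 0.5 at chrom starts
    chrom_slices: tuple       # ((code, start, stop), ...) in map order


def _map_info(gmap: pd.DataFrame) -> _MapInfo:
    gmap = validate_genetic_map(gmap)
    cm = gmap["cm"].to_numpy(dtype=float)
    chrom_id = pd.factorize(gmap["chrom"])[0]
    r = np.empty(len(cm))
    r[0] = 0.5
    if len(cm) > 1:
        same = chrom_id[1:] == chrom_id[:-1]
        r[1:] = np.where(same, _haldane(np.diff(cm)), 0.5)
    slices = []
    start = 0
    for i in range(1, len(cm) + 1):
        if i == len(cm) or chrom_id[i] != chrom_id[i - 1]:
            slices.append((int(chrom_id[start]), start, i))
            start = i
    return _MapInfo(cm=cm, chrom_id=chrom_id, r_full=r, chrom_slices=tuple(slices))


def _sub_r(info: _MapInfo, cols: np.ndarray) -> np.ndarray:
    """Switch probabilities restricted to a subset of marker columns.

    Exact under Haldane (the crossover process is Markov along the
    chromosome): adjacent retained markers recombine with the Haldane
    fraction of their cM distance, chromosome changes segregate freely.
    """
    cm = info.cm[cols]
    ch = info.chrom_id[cols]
    r = np.empty(len(cols))
    r[0] = 0.5
    if len(cols) > 1:
        same = ch[1:] == ch[:-1]
        r[1:] = np.where(same, _haldane(cm[1:] - cm[:-1]), 0.5)
    return r


def _gametes(parents: np.ndarray, r_full: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One gamete per parent, vectorised. ``parents`` is (n, 2, S) -> (n, S)."""
    n, _, s = parents.shape
    switches = rng.random((n, s)) < r_full
    src = np.cumsum(switches, axis=1) & 1
    return np.where(src == 0, parents[:, 0, :], parents[:, 1, :])


def meiosis(parent: np.ndarray, gmap: pd.DataFrame, rng: np.random.Generator) -> np.ndarray:
    """Single gamete from one parent via explicit Poisson crossovers.

    Per chromosome the crossover count is Poisson with mean span/100 (span
    in cM), positions are uniform on the marker span, and the gamete is the
    resulting mosaic of the two parental haplotypes starting from a random
    one. Marginally at the markers this is identical to the batch generator.
    """
    parent = np.asarray(parent)
    info = gmap if isinstance(gmap, _MapInfo) else _map_info(gmap)
    if parent.shape != (2, len(info.cm)):
        raise ValueError("parent haplotypes not aligned to the map")
    gamete = np.empty(len(info.cm), dtype=parent.dtype)
    for _, start, stop in info.chrom_slices:
        cm = info.cm[start:stop]
        span = float(cm[-1] - cm[0])
        k = rng.poisson(span / 100.0)
        xo = np.sort(rng.uniform(cm[0], cm[-1], size=k))
        which = (int(rng.integers(2)) + np.searchsorted(xo, cm, side="left")) & 1
        seg = np.where(which == 0, parent[0, start:stop], parent[1, start:stop])
        gamete[start:stop] = seg
    return gamete


# ---------------------------------------------------------------------------
# founders and the BC1S3 base population


@dataclass(frozen=True)
class Founders:
    """Recurrent elite parent plus fully inbred wild donors.

    Alleles are 0 (elite) / 1 (wild). Each wild donor carries the wild
    allele at its own random subset of markers (its polymorphism mask) and
    the elite allele elsewhere, so families segregate at different markers.
    """

    elite_hap: np.ndarray      # (S,) zeros
    wild_masks: np.ndarray     # (n_families, S) bool

    @property
    def n_families(self) -> int:
        return self.wild_masks.shape[0]


def make_founders(
    n_families: int,
    gmap: pd.DataFrame,
    wild_polymorphism_rate: float = 0.55,
    seed: int | np.random.SeedSequence | None = None,
) -> Founders:
    """Draw founder genomes for ``n_families`` donor × elite crosses.

    ``wild_polymorphism_rate`` is the fraction of markers at which a donor
    differs from the elite parent, drawn independently per family.
    """
    gmap = validate_genetic_map(gmap)
    n_snps = len(gmap)
    if n_snps == 0:
        raise ValueError("empty genetic map")
    if n_families < 1:
        raise ValueError("n_families must be >= 1")
    if not 0.0 < wild_polymorphism_rate <= 1.0:
        raise ValueError("wild_polymorphism_rate must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    masks = rng.random((n_families, n_snps)) < wild_polymorphism_rate
    return Founders(elite_hap=np.zeros(n_snps, dtype=np.int8), wild_masks=masks)


def make_bc1s3_population(
    founders: Founders,
    lines_per_family: int,
    gmap: pd.DataFrame,
    seed: int | np.random.SeedSequence | None = None,
) -> tuple[np.ndarray, GenotypeMatrix]:
    """Derive the genotyped base population: F1 -> BC1 -> three selfings.

    Every line descends from its family's F1 (donor × elite) backcrossed
    once to the elite parent, then advanced three generations by
    single-seed descent. Returns the plant genomes ``(n_lines, 2, S)`` and
    a :class:`GenotypeMatrix` of perfect single-plant calls (the integer
    call codes coincide with wild-allele dosage).
    """
    if lines_per_family < 1:
        raise ValueError("lines_per_family must be >= 1")
    gmap = validate_genetic_map(gmap)
    info = _map_info(gmap)
    rng = np.random.default_rng(seed)
    n_snps = len(gmap)
    blocks, ids, fams = [], [], []
    for f in range(founders.n_families):
        fam = f"F{f + 1:02d}"
        f1 = np.zeros((lines_per_family, 2, n_snps), dtype=np.int8)
        f1[:, 0, :] = founders.wild_masks[f].astype(np.int8)
        # BC1: one F1 gamete, one elite gamete
        cur = np.zeros_like(f1)
        cur[:, 0, :] = _gametes(f1, info.r_full, rng)
        for _ in range(3):  # S1..S3 single-seed descent
            nxt = np.stack(
                [_gametes(cur, info.r_full, rng), _gametes(cur, info.r_full, rng)],
                axis=1,
            )
            cur = nxt
        blocks.append(cur)
        ids.extend(f"{fam}_{i + 1:03d}" for i in range(lines_per_family))
        fams.extend([fam] * lines_per_family)
    genomes = np.concatenate(blocks, axis=0)
    calls = pd.DataFrame(
        genomes.sum(axis=1, dtype=np.int8), index=pd.Index(ids, name="line"),
        columns=gmap["snp"].tolist(),
    )
    family = pd.Series(fams, index=calls.index, name="family")
    return genomes, GenotypeMatrix(calls=calls, gmap=gmap, family=family)


# ---------------------------------------------------------------------------
# selection, propagation, pooling


@dataclass(frozen=True)
class SelectedLocus:
    """Per-locus fitness: 1 (elite hom), 1 + h*s (het), 1 + s (wild hom)."""

    snp: str
    s: float
    h: float = 0.5
    phase: str = "viability"

    def __post_init__(self) -> None:
        if self.phase not in ("viability", "harvest"):
            raise ValueError("phase must be 'viability' or 'harvest'")
        if not 0.0 <= self.h <= 1.0:
            raise ValueError("dominance h must lie in [0, 1]")
        if 1.0 + self.s <= 0.0 or 1.0 + self.h * self.s <= 0.0:
            raise ValueError("fitness values must be positive")

    def fitness(self) -> np.ndarray:
        return np.array([1.0, 1.0 + self.h * self.s, 1.0 + self.s])


@dataclass(frozen=True)
class SelectionModel:
    """Multiplicative per-locus fitness, split by acting phase.

    ``viability`` loci weight which sown seeds establish as plants;
    ``harvest`` loci weight which plants contribute harvested ears.
    An empty model is neutral.
    """

    loci: tuple[SelectedLocus, ...] = ()

    @classmethod
    def neutral(cls) -> "SelectionModel":
        return cls(())

    def phase_loci(self, phase: str) -> tuple[SelectedLocus, ...]:
        return tuple(l for l in self.loci if l.phase == phase)

    @property
    def is_neutral(self) -> bool:
        return len(self.loci) == 0

    def truth_table(self, gmap: pd.DataFrame) -> pd.DataFrame:
        """Ground-truth table of selected loci joined to map positions."""
        rows = [
            {"snp": l.snp, "s": l.s, "h": l.h, "phase": l.phase} for l in self.loci
        ]
        truth = pd.DataFrame(rows, columns=["snp", "s", "h", "phase"])
        return truth.merge(gmap, on="snp", how="left")[
            ["snp", "chrom", "cm", "s", "h", "phase"]
        ]


class _PhaseWeights:
    """Fitness evaluator for one phase, restricted to a column subset."""

    def __init__(self, loci, snp_to_col: dict, cols: np.ndarray):
        col_pos = {int(c): i for i, c in enumerate(cols)}
        self.dynamic: list[tuple[int, np.ndarray]] = []
        self.constant = 1.0
        self.max_weight = 1.0
        for locus in loci:
            if locus.snp not in snp_to_col:
                raise ValueError(f"selected locus {locus.snp!r} not in the map")
            fit = locus.fitness()
            col = snp_to_col[locus.snp]
            if col in col_pos:
                self.dynamic.append((col_pos[col], fit))
                self.max_weight *= fit.max()
            # loci fixed in this line contribute a constant factor
        self.max_weight *= self.constant

    def __call__(self, cohort: np.ndarray) -> np.ndarray:
        w = np.full(cohort.shape[0], self.constant)
        for pos, fit in self.dynamic:
            dosage = cohort[:, 0, pos].astype(np.intp) + cohort[:, 1, pos]
            w *= fit[dosage]
        return w


@dataclass(frozen=True)
class Season:
    """One season of plot propagation: plants sown, ears harvested."""

    n_sown: int
    n_ears: int

    def __post_init__(self) -> None:
        if self.n_sown < 1 or self.n_ears < 1:
            raise ValueError("season counts must be >= 1")
        if self.n_ears > self.n_sown:
            raise ValueError("cannot harvest more ears than plants sown")


@dataclass(frozen=True)
class PropagationSchedule:
    seasons: tuple[Season, ...]

    def __post_init__(self) -> None:
        if len(self.seasons) == 0:
            raise ValueError("propagation schedule is empty")

    @property
    def n_generations(self) -> int:
        return len(self.seasons)


def default_schedule() -> PropagationSchedule:
    """Five seasons of plot propagation with 20 ears harvested per season.

    Sowing counts follow the conservation design the pipeline models:
    a first plot of 60 plants, then 60, 60 and 100 seeds in the following
    seasons, and finally 20 plants from which seedlings are pooled.
    """
    return PropagationSchedule(
        seasons=(
            Season(60, 20),
            Season(60, 20),
            Season(60, 20),
            Season(100, 20),
            Season(20, 20),
        )
    )


def propagate_line(
    line_genome: np.ndarray,
    gmap: pd.DataFrame,
    schedule: PropagationSchedule,
    selection: SelectionModel | None = None,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """Propagate one line through the schedule; return the final cohort.

    Each season sows ``n_sown`` selfed seeds of the previous season's
    harvested mother plants (the first season selfs the input plant).
    Viability-phase fitness weights which seeds establish (rejection
    sampling against the maximal attainable weight); harvest-phase fitness
    weights which ``n_ears`` plants are chosen, without replacement, as
    mothers for the next season. The returned array is the final season's
    established cohort, shape ``(n_sown_last, 2, S)``.
    """
    selection = selection or SelectionModel.neutral()
    line_genome = np.asarray(line_genome, dtype=np.int8)
    info = gmap if isinstance(gmap, _MapInfo) else _map_info(gmap)
    if isinstance(gmap, _MapInfo):
        snp_to_col = getattr(info, "_snp_to_col", {})
    else:
        snp_to_col = {s: i for i, s in enumerate(validate_genetic_map(gmap)["snp"])}
    if line_genome.shape != (2, len(info.cm)):
        raise ValueError("line genome not aligned to the map")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    # only loci still segregating in this line can change: propagate the
    # heterozygous column subset and re-expand at the end (exact under the
    # Markov crossover model)
    seg_cols = np.nonzero(line_genome[0] != line_genome[1])[0]
    viab = _PhaseWeights(selection.phase_loci("viability"), snp_to_col, seg_cols)
    harv = _PhaseWeights(selection.phase_loci("harvest"), snp_to_col, seg_cols)

    final_n = schedule.seasons[-1].n_sown
    if len(seg_cols) == 0:
        # fully homozygous input: every descendant is identical
        return np.broadcast_to(line_genome, (final_n, 2, len(info.cm))).copy()

    r_sub = _sub_r(info, seg_cols)
    mothers = line_genome[:, seg_cols][np.newaxis]
    for i, season in enumerate(schedule.seasons):
        cohort = _sow(mothers, season.n_sown, r_sub, viab, rng)
        if i == len(schedule.seasons) - 1:
            break
        if harv.dynamic:
            w = harv(cohort)
            p = w / w.sum()
            chosen = rng.choice(season.n_sown, size=season.n_ears, replace=False, p=p)
        else:
            chosen = rng.choice(season.n_sown, size=season.n_ears, replace=False)
        mothers = cohort[chosen]

    full = np.broadcast_to(line_genome, (len(cohort), 2, len(info.cm))).copy()
    full[:, :, seg_cols] = cohort
    return full


def _sow(
    mothers: np.ndarray,
    n: int,
    r_sub: np.ndarray,
    viab: _PhaseWeights,
    rng: np.random.Generator,
) -> np.ndarray:
    """n established selfed seedlings of the mothers, after viability selection."""
    idx = rng.integers(0, len(mothers), size=n)
    parents = mothers[idx]
    cohort = np.stack(
        [_gametes(parents, r_sub, rng), _gametes(parents, r_sub, rng)], axis=1
    )
    if not viab.dynamic:
        return cohort
    # rejection sampling: each candidate establishes with prob w/w_max
    alive = rng.random(n) * viab.max_weight <= viab(cohort)
    while not alive.all():
        m = np.nonzero(~alive)[0]
        idx = rng.integers(0, len(mothers), size=len(m))
        parents = mothers[idx]
        redo = np.stack(
            [_gametes(parents, r_sub, rng), _gametes(parents, r_sub, rng)], axis=1
        )
        cohort[m] = redo
        alive[m] = rng.random(len(m)) * viab.max_weight <= viab(redo)
    return cohort


def pool_and_call(
    cohort: np.ndarray,
    pool_size: int = 12,
    minor_tolerance: float = 0.2,
    failure_rate: float = 0.0,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
) -> np.ndarray:
    """Tolerance-based allele call of a pooled DNA sample.

    ``pool_size`` plants are sampled uniformly without replacement; per
    marker, if the minor-allele fraction over the 2 × pool_size allele
    copies is at most ``minor_tolerance`` the majority homozygote is
    called, otherwise the call is heterozygous (reconstructed
    heterozygosity). Each call fails independently with ``failure_rate``.
    Returns one call code per marker.
    """
    cohort = np.asarray(cohort)
    if pool_size > cohort.shape[0]:
        raise ValueError("pool_size exceeds cohort size")
    if pool_size < 1:
        raise ValueError("pool_size must be >= 1")
    if not 0.0 <= minor_tolerance < 0.5:
        raise ValueError("minor_tolerance must lie in [0, 0.5)")
    if not 0.0 <= failure_rate <= 1.0:
        raise ValueError("failure_rate must lie in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    picked = rng.choice(cohort.shape[0], size=pool_size, replace=False)
    wild = cohort[picked].sum(axis=(0, 1), dtype=np.int64)
    total = 2 * pool_size
    minor = np.minimum(wild, total - wild)
    calls = np.where(
        minor / total <= minor_tolerance,
        np.where(wild * 2 > total, 2, 0),  # majority homozygote
        1,
    ).astype(np.int8)
    if failure_rate > 0.0:
        calls[rng.random(len(calls)) < failure_rate] = -1
    return calls


# ---------------------------------------------------------------------------
# end-to-end experiment


@dataclass(frozen=True)
class ExperimentConfig:
    """Everything needed to simulate one paired-generation experiment.

    Defaults follow the conservation design being modelled: 25 families,
    ~57 lines each (≈1,400 lines), donors polymorphic at 55% of markers,
    the five-season default schedule, 12-plant pooling with a 20%
    minor-allele calling tolerance and a 1% no-call rate.
    """

    gmap: pd.DataFrame
    n_families: int = 25
    lines_per_family: int = 57
    wild_polymorphism_rate: float = 0.55
    schedule: PropagationSchedule = field(default_factory=default_schedule)
    selection: SelectionModel = field(default_factory=SelectionModel.neutral)
    pool_size: int = 12
    minor_tolerance: float = 0.2
    failure_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pool_size > self.schedule.seasons[-1].n_sown:
            raise ValueError("pool_size exceeds the final-season cohort")


@dataclass
class SimulationResult:
    """Paired genotype matrices plus the ground truth that produced them."""

    g0: GenotypeMatrix
    g8: GenotypeMatrix
    truth: pd.DataFrame
    log: dict


def simulate_experiment(config: ExperimentConfig) -> SimulationResult:
    """Simulate the full design: base population, propagation, pooled calls.

    Returns perfect single-plant calls for the base generation (``g0``),
    pooled tolerance-based calls for the final generation (``g8``) on the
    same lines and markers, the ground-truth table of selected loci, and a
    small run log. Fully reproducible from ``config.seed``.
    """
    gmap = validate_genetic_map(config.gmap)
    root = np.random.SeedSequence(config.seed)
    ss_founders, ss_pop, ss_lines = root.spawn(3)
    founders = make_founders(
        config.n_families, gmap, config.wild_polymorphism_rate, seed=ss_founders
    )
    genomes, g0 = make_bc1s3_population(
        founders, config.lines_per_family, gmap, seed=ss_pop
    )
    info = _map_info(gmap)
    snp_to_col = {s: i for i, s in enumerate(gmap["snp"])}
    object.__setattr__(info, "_snp_to_col", snp_to_col)

    n_lines = genomes.shape[0]
    line_seeds = ss_lines.spawn(n_lines)
    g8_calls = np.empty((n_lines, len(gmap)), dtype=np.int8)
    for i in range(n_lines):
        rng = np.random.default_rng(line_seeds[i])
        cohort = propagate_line(
            genomes[i], info, config.schedule, config.selection, seed=rng
        )
        g8_calls[i] = pool_and_call(
            cohort,
            pool_size=config.pool_size,
            minor_tolerance=config.minor_tolerance,
            failure_rate=config.failure_rate,
            seed=rng,
        )
    g8 = GenotypeMatrix(
        calls=pd.DataFrame(g8_calls, index=g0.lines.copy(), columns=list(g0.snps)),
        gmap=gmap,
        family=g0.family.copy(),
    )
    truth = config.selection.truth_table(gmap)
    log = {
        "n_lines": int(n_lines),
        "n_snps": int(len(gmap)),
        "n_families": int(config.n_families),
        "n_selfing_generations": int(config.schedule.n_generations),
        "n_selected_loci": int(len(config.selection.loci)),
        "seed": int(config.seed),
    }
    return SimulationResult(g0=g0, g8=g8, truth=truth, log=log)
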