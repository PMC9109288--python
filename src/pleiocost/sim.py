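"""Forward simulation of polygenic adaptation with pleiotropic costs.

Individual-based diploid Wright–Fisher model in two phases:

1. *Adaptation*: replicate populations founded from a common standing-variation
   pool adapt to a shifted trait optimum under Gaussian stabilizing selection.
   Each beneficial allele also carries a multiplicative pleiotropic fitness
   cost whose expression in heterozygotes is controlled by a dominance
   coefficient (fully recessive costs are masked in heterozygous carriers).
2. *Admixture*: two independently adapted replicates are mixed in an
   imbalanced ratio (default 15:85) and the mixture evolves further under the
   same selection regime.

Pool-Seq sampling (pooled individuals, binomial read resampling at a fixed or
Poisson depth) turns population states into synthetic sequencing counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

BASES = ("A", "T", "C", "G")


class ExtinctionError(RuntimeError):
    """Raised when every individual has zero fitness."""


def default_effect_sizes(n_loci: int, large_effect: float = 1.0,
                         small_effect: float = 0.15) -> np.ndarray:
    """L-shaped trait architecture: roughly a third of the loci carry large
    effects (the redundant adaptive reservoir from which each replicate's
    selected subset is drawn), the rest small effects that contribute mostly
    pleiotropic load.  Empirical effect-size distributions of polygenic
    traits are strongly skewed in this way."""
    a = np.full(n_loci, small_effect)
    a[: max(n_loci // 3, 1)] = large_effect
    return a


def default_init_freqs(n_loci: int, rare: float = 0.005, common: float = 0.08) -> np.ndarray:
    """Founder frequencies matching the effect-size architecture: the
    large-effect reservoir segregates as rare variants (a handful of copies
    in the founder, so early drift decides which loci sweep in which
    replicate — the redundancy lottery), while the weak-effect background
    segregates at common-variant frequencies."""
    p = np.full(n_loci, common)
    p[: max(n_loci // 3, 1)] = rare
    return p


def _locus_array(value, n_loci: int, name: str) -> np.ndarray:
    arr = np.broadcast_to(np.asarray(value, dtype=float), (n_loci,)).copy()
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


@dataclass
class SimConfig:
    """Full parameterization of the two-phase experiment.

    Trait model: an individual's trait value is z = sum_i a_i * g(d_i, G_i)
    with g mapping genotypes {0, 1, 2 beneficial copies} to {0, 2*d_i, 2}, so
    an additive locus (d = 0.5) contributes {0, a_i, 2*a_i}.  Fitness is
    Gaussian stabilizing selection around the current optimum,
    exp(-(z - theta)^2 / (2 * omega^2)), multiplied by per-locus pleiotropic
    cost terms (1 - c_i * eta_i) with eta = {0, h_c, 1} for {0, 1, 2} copies
    of the beneficial allele.
    """

    census_size: int = 1250
    n_loci: int = 60
    effect_sizes: Optional[float | np.ndarray] = None  # default: L-shaped architecture
    init_freqs: Optional[float | np.ndarray] = None    # default: rare/common mix
    optimum_old: Optional[float] = None   # default: founder mean trait value
    optimum_new: Optional[float] = None   # default: optimum_old + optimum_shift
    optimum_shift: float = 16.0
    selection_width: float = 8.0          # omega; inf => flat trait fitness
    trait_dominance: float | np.ndarray = 0.5
    cost_per_locus: float | np.ndarray = 0.05
    cost_dominance: float = 0.0           # h_c; 0 = fully recessive cost
    recomb_fraction: Optional[float | np.ndarray] = None  # None = free recomb
    adapt_generations: int = 110
    mix_generations: int = 29
    mix_proportion: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.census_size < 2:
            raise ValueError("census_size must be >= 2")
        if self.effect_sizes is None:
            self.effect_sizes = default_effect_sizes(self.n_loci)
        if self.init_freqs is None:
            self.init_freqs = default_init_freqs(self.n_loci)
        self.effect_sizes = _locus_array(self.effect_sizes, self.n_loci, "effect_sizes")
        self.init_freqs = _locus_array(self.init_freqs, self.n_loci, "init_freqs")
        if np.any((self.init_freqs < 0) | (self.init_freqs > 1)):
            raise ValueError("init_freqs must lie in [0, 1]")
        self.trait_dominance = _locus_array(self.trait_dominance, self.n_loci, "trait_dominance")
        if np.any((self.trait_dominance < 0) | (self.trait_dominance > 1)):
            raise ValueError("trait_dominance must lie in [0, 1]")
        self.cost_per_locus = _locus_array(self.cost_per_locus, self.n_loci, "cost_per_locus")
        if np.any((self.cost_per_locus < 0) | (self.cost_per_locus >= 1)):
            raise ValueError("cost_per_locus must lie in [0, 1)")
        if not 0.0 <= self.cost_dominance <= 1.0:
            raise ValueError("cost_dominance must lie in [0, 1]")
        if not 0.0 < self.mix_proportion < 1.0:
            raise ValueError("mix_proportion must lie in (0, 1)")
        if self.selection_width is not None and self.selection_width <= 0 and np.isfinite(self.selection_width):
            raise ValueError("selection_width must be positive (use inf for a flat fitness surface)")
        if self.recomb_fraction is not None:
            self.recomb_fraction = _locus_array(self.recomb_fraction, max(self.n_loci - 1, 1), "recomb_fraction")
            if np.any((self.recomb_fraction < 0) | (self.recomb_fraction > 0.5)):
                raise ValueError("recomb_fraction must lie in [0, 0.5]")
        if self.optimum_old is None:
            self.optimum_old = float(2.0 * np.sum(self.effect_sizes * self.init_freqs))
        if self.optimum_new is None:
            self.optimum_new = self.optimum_old + self.optimum_shift


@dataclass
class PoolSeqConfig:
    """Pool-Seq sampling: pooled individuals, then binomial read counts."""

    coverage: float = 50.0
    coverage_model: str = "poisson"  # "fixed" or "poisson"
    pool_size: Optional[int] = None  # default: whole census

    def __post_init__(self):
        if self.coverage < 1:
            raise ValueError("coverage must be >= 1")
        if self.coverage_model not in ("fixed", "poisson"):
            raise ValueError("coverage_model must be 'fixed' or 'poisson'")


@dataclass
class PopulationState:
    """Diploid genotype state: haplotypes[i, k, l] = 1 iff individual i's
    haplotype k carries the beneficial allele at locus l."""

    haplotypes: np.ndarray                      # (N, 2, L) uint8
    generation: int = 0
    lineage_labels: Optional[np.ndarray] = None  # (N, 2, L) uint8; 1 = immigrant

    @property
    def census_size(self) -> int:
        return self.haplotypes.shape[0]

    @property
    def n_loci(self) -> int:
        return self.haplotypes.shape[2]

    def allele_freqs(self) -> np.ndarray:
        return self.haplotypes.mean(axis=(0, 1))

    def copy(self) -> "PopulationState":
        return PopulationState(
            self.haplotypes.copy(),
            self.generation,
            None if self.lineage_labels is None else self.lineage_labels.copy(),
        )


def founder_population(cfg: SimConfig, rng: np.random.Generator) -> PopulationState:
    """Draw founder haplotypes by independent per-locus Bernoulli(init_freq)
    (linkage equilibrium at generation 0)."""
    haps = (rng.random((cfg.census_size, 2, cfg.n_loci)) < cfg.init_freqs).astype(np.uint8)
    return PopulationState(haps, generation=0)


def trait_values(genotypes: np.ndarray, cfg: SimConfig) -> np.ndarray:
    """Trait z per individual from genotype dosage matrix (N, L) in {0,1,2}."""
    het = genotypes == 1
    hom = genotypes == 2
    contrib = het * (2.0 * cfg.trait_dominance) + hom * 2.0
    return contrib @ cfg.effect_sizes


def population_fitness(pop: PopulationState, cfg: SimConfig, optimum: float) -> np.ndarray:
    g = pop.haplotypes.sum(axis=1)
    z = trait_values(g, cfg)
    if not np.all(np.isfinite(z)):
        raise ValueError("non-finite trait value")
    if np.isfinite(cfg.selection_width):
        w = np.exp(-((z - optimum) ** 2) / (2.0 * cfg.selection_width**2))
    else:
        w = np.ones_like(z)
    # pleiotropic load: product over loci of (1 - c * eta)
    eta = (g == 1) * cfg.cost_dominance + (g == 2) * 1.0
    w *= np.exp(np.log1p(-cfg.cost_per_locus * eta).sum(axis=1))
    return w


def individual_fitness(hap1: np.ndarray, hap2: np.ndarray, cfg: SimConfig, optimum: float) -> float:
    """Fitness of a single diploid given its two 0/1 haplotype vectors."""
    haps = np.stack([np.asarray(hap1, dtype=np.uint8), np.asarray(hap2, dtype=np.uint8)])[None]
    if haps.shape[2] != cfg.n_loci:
        raise ValueError(f"haplotypes must have length {cfg.n_loci}")
    return float(population_fitness(PopulationState(haps), cfg, optimum)[0])


def _transmission_masks(cfg: SimConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Which parental haplotype (0/1) each transmitted allele comes from."""
    L = cfg.n_loci
    if cfg.recomb_fraction is None:  # free recombination
        return rng.integers(0, 2, size=(n, 2, L), dtype=np.uint8)
    start = rng.integers(0, 2, size=(n, 2, 1), dtype=np.uint8)
    if L == 1:
        return start
    switches = (rng.random((n, 2, L - 1)) < cfg.recomb_fraction).astype(np.uint8)
    return (np.cumsum(np.concatenate([start, switches], axis=2), axis=2) % 2).astype(np.uint8)


def advance_generation(
    pop: PopulationState, cfg: SimConfig, optimum: float, rng: np.random.Generator
) -> PopulationState:
    """One non-overlapping Wright–Fisher generation with fitness-weighted
    parent sampling and Mendelian transmission of recombinant haplotypes."""
    n = pop.census_size
    w = population_fitness(pop, cfg, optimum)
    total = w.sum()
    if total <= 0:
        raise ExtinctionError("population extinct under selection")
    parents = rng.choice(n, size=(n, 2), p=w / total)
    masks = _transmission_masks(cfg, n, rng)
    locus_idx = np.arange(cfg.n_loci)[None, None, :]
    children = pop.haplotypes[parents[:, :, None], masks, locus_idx]
    labels = None
    if pop.lineage_labels is not None:
        labels = pop.lineage_labels[parents[:, :, None], masks, locus_idx]
    return PopulationState(np.ascontiguousarray(children), pop.generation + 1, labels)


def evolve(
    pop: PopulationState,
    cfg: SimConfig,
    optimum: float,
    n_generations: int,
    rng: np.random.Generator,
    record: bool = True,
):
    """Run n_generations; returns (trajectory, final state).  The trajectory
    has one row per generation including the starting state
    (shape (n_generations + 1, L)); None when record=False."""
    traj = np.empty((n_generations + 1, cfg.n_loci)) if record else None
    if record:
        traj[0] = pop.allele_freqs()
    for t in range(n_generations):
        pop = advance_generation(pop, cfg, optimum, rng)
        if record:
            traj[t + 1] = pop.allele_freqs()
    return traj, pop


def adapt(pop: PopulationState, cfg: SimConfig, rng: np.random.Generator):
    """Phase 1: adapt_generations of selection toward the new optimum."""
    return evolve(pop, cfg, cfg.optimum_new, cfg.adapt_generations, rng)


def admix(
    pop_immigrant: PopulationState,
    pop_recipient: PopulationState,
    m: float,
    n: int,
    rng: np.random.Generator,
) -> PopulationState:
    """Imbalanced mixture: the immigrant count is binomial around m*n,
    mirroring stochastic sampling of individuals at experiment setup."""
    if not 0.0 < m < 1.0:
        raise ValueError("mixture proportion m must lie in (0, 1)")
    if pop_immigrant.n_loci != pop_recipient.n_loci:
        raise ValueError("populations must share locus indexing")
    n_imm = int(rng.binomial(n, m))
    n_imm = min(n_imm, pop_immigrant.census_size)
    n_rec = min(n - n_imm, pop_recipient.census_size)
    idx_imm = rng.choice(pop_immigrant.census_size, size=n_imm, replace=False)
    idx_rec = rng.choice(pop_recipient.census_size, size=n_rec, replace=False)
    haps = np.concatenate([pop_immigrant.haplotypes[idx_imm], pop_recipient.haplotypes[idx_rec]])
    labels = np.zeros_like(haps)
    labels[:n_imm] = 1
    return PopulationState(haps, generation=0, lineage_labels=labels)


def pool_seq_sample(pop: PopulationState, psc: PoolSeqConfig, rng: np.random.Generator):
    """Two-stage Pool-Seq noise: (1) allele frequency of a pool of individuals
    sampled without replacement, (2) binomial read counts at the site depth.

    Returns (beneficial_counts, depths), each of length L.
    """
    pool_size = psc.pool_size if psc.pool_size is not None else pop.census_size
    if pool_size > pop.census_size:
        raise ValueError("pool_size exceeds census size")
    idx = rng.choice(pop.census_size, size=pool_size, replace=False)
    pool_freq = pop.haplotypes[idx].mean(axis=(0, 1))
    if psc.coverage_model == "fixed":
        depth = np.full(pop.n_loci, int(round(psc.coverage)), dtype=np.int64)
    else:
        depth = rng.poisson(psc.coverage, size=pop.n_loci)
    counts = rng.binomial(depth, pool_freq)
    return counts, depth


# ---------------------------------------------------------------------------
# Experiment orchestration
# ---------------------------------------------------------------------------

@dataclass
class Design:
    """Which parental replicates exist, which share early history, and which
    ordered (immigrant, recipient) mixtures are set up.

    shared_history groups replicates that evolve together for the stated
    number of generations before branching — emulating replicate pairs that
    adapted via overlapping locus sets (lowly differentiated pairs).
    """

    parental_ids: tuple[str, ...] = ("R1", "R2", "R3", "R4")
    shared_history: dict = field(default_factory=lambda: {("R1", "R2"): 80})
    pairs: tuple[tuple[str, str], ...] = (
        ("R1", "R2"), ("R2", "R1"), ("R3", "R4"), ("R4", "R3"),
    )
    n_mix_replicates: int = 3
    parental_extra: tuple[int, ...] = (10, 20)   # sampled gens after adaptation
    mixed_timepoints: tuple[int, ...] = (1, 20, 29)
    selected_delta: float = 0.3   # truth flag: delta-p(0->110) above this

    def __post_init__(self):
        for imm, rec in self.pairs:
            for rep in (imm, rec):
                if rep not in self.parental_ids:
                    raise ValueError(f"pair references unknown replicate {rep!r}")
        claimed = [r for grp in self.shared_history for r in grp]
        if len(claimed) != len(set(claimed)):
            raise ValueError("a replicate may belong to at most one shared-history group")
        for grp in self.shared_history:
            for rep in grp:
                if rep not in self.parental_ids:
                    raise ValueError(f"shared_history references unknown replicate {rep!r}")

    def pair_label(self, imm: str, rec: str) -> str:
        return f"{imm}->{rec}"


@dataclass
class ExperimentDataset:
    """Everything downstream inference consumes: observed Pool-Seq counts for
    parental and mixed populations at every sampled generation, plus the
    simulation ground truth (absent for real data)."""

    loci: pd.DataFrame                      # truth table, one row per locus
    parental_counts: dict                   # rep -> {gen: (counts, depth)}
    mixed_counts: dict                      # pair label -> [ {gen: (counts, depth)} per mix replicate ]
    trajectories: dict                      # rep -> (adapt_generations+1, L) true freqs
    config: SimConfig
    poolseq: PoolSeqConfig
    design: Design
    seed: int

    def parental_freqs(self, rep: str) -> pd.DataFrame:
        """Observed beneficial-allele frequencies, loci x sampled generations."""
        data = {}
        for gen, (counts, depth) in self.parental_counts[rep].items():
            with np.errstate(invalid="ignore", divide="ignore"):
                data[gen] = np.where(depth > 0, counts / np.maximum(depth, 1), np.nan)
        return pd.DataFrame(data, index=self.loci.index)

    def mixed_freqs(self, pair: str, mix_rep: int) -> pd.DataFrame:
        data = {}
        for gen, (counts, depth) in self.mixed_counts[pair][mix_rep].items():
            with np.errstate(invalid="ignore", divide="ignore"):
                data[gen] = np.where(depth > 0, counts / np.maximum(depth, 1), np.nan)
        return pd.DataFrame(data, index=self.loci.index)


def _stream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-role RNG stream; adding replicates or pairs never
    perturbs the streams of existing ones."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, *key]))


def _assign_locus_bases(n_loci: int, seed: int):
    rng = _stream(seed, 6)
    ref_idx = rng.integers(0, 4, size=n_loci)
    offset = rng.integers(1, 4, size=n_loci)
    alt_idx = (ref_idx + offset) % 4
    ref = [BASES[i] for i in ref_idx]
    alt = [BASES[i] for i in alt_idx]
    return ref, alt


def run_experiment(cfg: SimConfig, psc: PoolSeqConfig, design: Design, seed: Optional[int] = None) -> ExperimentDataset:
    """Simulate the full experiment.

    Parental replicates share one founder population; shared-history groups
    additionally evolve together before branching.  At the end of adaptation
    every designed (immigrant, recipient) mixture is set up in
    n_mix_replicates independent 15:85 admixtures and evolved onward.
    Pool-Seq samples are drawn for parents at generations
    {0, T, T+10, T+20} (T = adapt_generations) and mixtures at F1/F20/F29.
    """
    if seed is None:
        seed = cfg.seed
    founder = founder_population(cfg, _stream(seed, 0))
    rep_index = {rep: i for i, rep in enumerate(design.parental_ids)}

    # --- phase 1: adaptation, with optional shared early history per group
    group_of = {}
    for gi, (grp, gens) in enumerate(sorted(design.shared_history.items(),
                                            key=lambda kv: min(rep_index[r] for r in kv[0]))):
        if gens > cfg.adapt_generations:
            raise ValueError("shared history cannot exceed adapt_generations")
        for rep in grp:
            group_of[rep] = (gi, gens)
    shared_state: dict[int, tuple[np.ndarray, PopulationState]] = {}
    trajectories = {}
    pop110 = {}
    for rep in design.parental_ids:
        if rep in group_of:
            gi, shared_gens = group_of[rep]
            if gi not in shared_state:
                traj_s, pop_s = evolve(founder.copy(), cfg, cfg.optimum_new, shared_gens,
                                       _stream(seed, 5, gi))
                shared_state[gi] = (traj_s, pop_s)
            traj_s, pop_s = shared_state[gi]
            traj_r, pop_r = evolve(pop_s.copy(), cfg, cfg.optimum_new,
                                   cfg.adapt_generations - shared_gens,
                                   _stream(seed, 1, rep_index[rep]))
            traj = np.vstack([traj_s, traj_r[1:]])
        else:
            traj, pop_r = evolve(founder.copy(), cfg, cfg.optimum_new,
                                 cfg.adapt_generations, _stream(seed, 1, rep_index[rep]))
        trajectories[rep] = traj
        pop110[rep] = pop_r

    # --- parental continuation (still under selection at the new optimum)
    t_adapt = cfg.adapt_generations
    parental_states = {rep: {0: founder, t_adapt: pop110[rep]} for rep in design.parental_ids}
    for rep in design.parental_ids:
        rng = _stream(seed, 2, rep_index[rep])
        state = pop110[rep]
        prev = t_adapt
        for extra in design.parental_extra:
            _, state = evolve(state.copy(), cfg, cfg.optimum_new, (t_adapt + extra) - prev,
                              rng, record=False)
            parental_states[rep][t_adapt + extra] = state
            prev = t_adapt + extra

    # --- phase 2: imbalanced mixtures
    mixed_states: dict[str, list[dict[int, PopulationState]]] = {}
    for pi, (imm, rec) in enumerate(design.pairs):
        label = design.pair_label(imm, rec)
        mixed_states[label] = []
        for mrep in range(design.n_mix_replicates):
            rng = _stream(seed, 3, pi, mrep)
            pop = admix(pop110[imm], pop110[rec], cfg.mix_proportion, cfg.census_size, rng)
            snapshots = {}
            gen = 0
            for tp in sorted(design.mixed_timepoints):
                _, pop = evolve(pop, cfg, cfg.optimum_new, tp - gen, rng, record=False)
                snapshots[tp] = pop
                gen = tp
            mixed_states[label].append(snapshots)

    # --- Pool-Seq sampling (independent noise per sample, stable stream ids)
    parental_counts = {}
    for rep in design.parental_ids:
        parental_counts[rep] = {}
        for ti, gen in enumerate(sorted(parental_states[rep])):
            rng = _stream(seed, 4, 0, rep_index[rep], ti)
            parental_counts[rep][gen] = pool_seq_sample(parental_states[rep][gen], psc, rng)
    mixed_counts = {}
    for pi, (imm, rec) in enumerate(design.pairs):
        label = design.pair_label(imm, rec)
        mixed_counts[label] = []
        for mrep in range(design.n_mix_replicates):
            per_tp = {}
            for ti, gen in enumerate(sorted(design.mixed_timepoints)):
                rng = _stream(seed, 4, 1, pi, mrep, ti)
                per_tp[gen] = pool_seq_sample(mixed_states[label][mrep][gen], psc, rng)
            mixed_counts[label].append(per_tp)

    # --- truth table
    ref, alt = _assign_locus_bases(cfg.n_loci, seed)
    loci = pd.DataFrame({
        "locus": np.arange(cfg.n_loci),
        "chrom": "sim1",
        "pos": 1000 * (np.arange(cfg.n_loci) + 1),
        "ref": ref,
        "beneficial_base": alt,
        "effect_size": cfg.effect_sizes,
        "cost": cfg.cost_per_locus,
        "init_freq": cfg.init_freqs,
    }).set_index("locus")
    for rep in design.parental_ids:
        dp = trajectories[rep][-1] - trajectories[rep][0]
        loci[f"q110_{rep}"] = trajectories[rep][-1]
        loci[f"selected_{rep}"] = dp > design.selected_delta
    return ExperimentDataset(loci, parental_counts, mixed_counts, trajectories,
                             cfg, psc, design, seed)
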