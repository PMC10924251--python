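"""Serial-passage directed evolution under an error-prone polymerase.

Each round emulates one overnight passage of a phage population carrying an
evolvable locus: the round's founders amplify in expectation proportionally
to 10**F of their genotype (a selective-sweep / Wright–Fisher update at
population size ``burst_pop``), every replicated genome acquires
Poisson-distributed substitutions at the error-prone rate, and the burst is
bottlenecked back to ``founders`` particles to seed the next round. The
default parameters mirror the assay this emulates: ~1e5 founding particles,
10 rounds, and a mutator polymerase with a ~1,000-fold elevated error rate.

Genotypes are sets of DNA substitutions on the locus; log10 fitness is
additive over their amino-acid effects (no epistasis). Stop-gain genomes
are non-viable by default. Dominant-mutation calling emulates Sanger
consensus sequencing of the population: a mutation is visible only once its
frequency exceeds the consensus threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codons import translate_codon
from .variant_model import ProteinTarget

#: a genotype is a frozenset of (0-based DNA position, alternate base)
Genotype = frozenset[tuple[int, str]]
WT_GENOTYPE: Genotype = frozenset()
_BASES = "ACGT"


@dataclass
class EvolutionConfig:
    """Parameters of one directed-evolution campaign."""

    genome: ProteinTarget
    fitness_effects: dict[str, float]  # amino-acid variant name -> ΔF (log10)
    base_fitness: float = 0.0
    rounds: int = 10
    founders: int = 100_000
    burst_pop: int = 100_000
    mut_rate: float = 2e-8  # per base per replication, wild-type polymerase
    mutator_factor: float = 1000.0
    consensus_threshold: float = 0.5
    stop_lethal: bool = True
    mutation_bias: np.ndarray | None = None  # 4x4 row-stochastic, ACGT order
    seed: int = 0

    def __post_init__(self) -> None:
        if self.founders > self.burst_pop:
            raise ValueError("founders must not exceed burst_pop")
        if not 0 < self.consensus_threshold < 1:
            raise ValueError("consensus_threshold must be in (0, 1)")
        if self.mut_rate * self.mutator_factor >= 0.1:
            raise ValueError("effective per-base mutation rate must be < 0.1")
        if self.mutation_bias is not None:
            bias = np.asarray(self.mutation_bias, dtype=float)
            if bias.shape != (4, 4) or not np.allclose(bias.sum(axis=1), 1.0):
                raise ValueError("mutation_bias must be 4x4 row-stochastic")
            self.mutation_bias = bias

    @property
    def effective_rate(self) -> float:
        return self.mut_rate * self.mutator_factor


@dataclass
class EvolutionTrajectory:
    """Per-round mutation frequencies and Sanger-style dominant calls."""

    table: pd.DataFrame  # round, mutation, aa_effect, frequency
    dominant_calls: dict[int, list[str]] = field(default_factory=dict)
    fixation_round: dict[str, int] = field(default_factory=dict)
    seed: int | None = None

    def frequencies(self, round_idx: int) -> dict[str, float]:
        sub = self.table.loc[self.table["round"] == round_idx]
        return dict(zip(sub["mutation"], sub["frequency"]))


class _FitnessCache:
    """Genotype -> (log10 fitness, viability), with amino-acid effect lookup."""

    def __init__(self, config: EvolutionConfig):
        self.cfg = config
        self.dna = config.genome.dna_seq
        self.aa = config.genome.aa_seq
        self.cache: dict[Genotype, tuple[float, bool]] = {
            WT_GENOTYPE: (config.base_fitness, True)
        }
        self.effect_cache: dict[tuple[tuple[int, str], ...], list[str]] = {}

    def aa_effects(self, genotype: Genotype) -> list[str]:
        """Amino-acid-level labels of a genotype's substitutions."""
        key = tuple(sorted(genotype))
        hit = self.effect_cache.get(key)
        if hit is not None:
            return hit
        by_codon: dict[int, list[tuple[int, str]]] = {}
        for pos, alt in genotype:
            by_codon.setdefault(pos // 3, []).append((pos, alt))
        labels = []
        for ci, subs in sorted(by_codon.items()):
            codon = list(self.dna[3 * ci : 3 * ci + 3])
            for pos, alt in subs:
                codon[pos % 3] = alt
            new_aa = translate_codon("".join(codon))
            wt_aa = self.aa[ci]
            if new_aa != wt_aa:
                labels.append(f"{wt_aa}{ci + 1}{new_aa}")
        self.effect_cache[key] = labels
        return labels

    def fitness(self, genotype: Genotype) -> tuple[float, bool]:
        hit = self.cache.get(genotype)
        if hit is not None:
            return hit
        F = self.cfg.base_fitness
        viable = True
        for label in self.aa_effects(genotype):
            if label.endswith("*"):
                if self.cfg.stop_lethal:
                    viable = False
                    break
            else:
                F += self.cfg.fitness_effects.get(label, 0.0)
        result = (F, viable)
        self.cache[genotype] = result
        return result


def mutation_label(pos: int, alt: str, dna: str) -> str:
    """DNA-level label for a substitution, e.g. ``256A>C`` (1-based)."""
    return f"{pos + 1}{dna[pos]}>{alt}"


def _mutate(
    pop: dict[Genotype, int], config: EvolutionConfig, rng: np.random.Generator
) -> dict[Genotype, int]:
    """Apply Poisson substitution mutagenesis to every genome of ``pop``."""
    L = len(config.genome.dna_seq)
    lam = config.effective_rate * L
    if lam == 0:
        return pop
    p_any = -math.expm1(-lam)
    dna = config.genome.dna_seq
    bias = config.mutation_bias
    out: dict[Genotype, int] = {}
    for genotype, count in pop.items():
        k = rng.binomial(count, p_any)
        if count - k:
            out[genotype] = out.get(genotype, 0) + (count - k)
        for _ in range(k):
            m = _sample_ztp(lam, rng)
            muts = dict(genotype)
            for pos in rng.integers(0, L, size=m):
                pos = int(pos)
                ref = dna[pos]
                cur = muts.get(pos, ref)
                alt = _draw_base(cur, bias, rng)
                if alt == ref:
                    muts.pop(pos, None)  # reversion to wild type
                else:
                    muts[pos] = alt
            g = frozenset(muts.items())
            out[g] = out.get(g, 0) + 1
    return out


def _sample_ztp(lam: float, rng: np.random.Generator) -> int:
    """Zero-truncated Poisson draw by inverse CDF (lam is small here)."""
    u = rng.random()
    denom = math.expm1(lam)
    term = lam  # lam^m / m! at m = 1
    cum = term / denom
    m = 1
    while u > cum and m < 200:
        m += 1
        term *= lam / m
        cum += term / denom
    return m


def _draw_base(current: str, bias: np.ndarray | None, rng: np.random.Generator) -> str:
    i = _BASES.index(current)
    if bias is None:
        j = (i + int(rng.integers(1, 4))) % 4
        return _BASES[j]
    return _BASES[int(rng.choice(4, p=bias[i]))]


def advance_round(
    pop: dict[Genotype, int],
    config: EvolutionConfig,
    rng: np.random.Generator,
    cache: _FitnessCache | None = None,
) -> dict[Genotype, int]:
    """One passage: selective amplification to ``burst_pop``, then mutation.

    Expected post-amplification frequency of a genotype with advantage
    s = 10**ΔF over the rest follows f' = s f / (s f + (1 − f)).
    """
    cache = cache or _FitnessCache(config)
    genotypes = list(pop)
    counts = np.array([pop[g] for g in genotypes], dtype=float)
    fits = np.array([cache.fitness(g)[0] for g in genotypes])
    viable = np.array([cache.fitness(g)[1] for g in genotypes])
    w = counts * np.power(10.0, fits) * viable
    if w.sum() <= 0:
        raise RuntimeError("population extinct: no viable genomes")
    burst = rng.multinomial(config.burst_pop, w / w.sum())
    amplified = {g: int(n) for g, n in zip(genotypes, burst) if n > 0}
    return _mutate(amplified, config, rng)


def _bottleneck(
    pop: dict[Genotype, int], founders: int, rng: np.random.Generator
) -> dict[Genotype, int]:
    genotypes = list(pop)
    counts = np.array([pop[g] for g in genotypes], dtype=float)
    total = counts.sum()
    if total <= founders:
        return dict(pop)
    drawn = rng.multinomial(founders, counts / total)
    return {g: int(n) for g, n in zip(genotypes, drawn) if n > 0}


def _mutation_frequencies(
    pop: dict[Genotype, int], cache: _FitnessCache, dna: str
) -> pd.DataFrame:
    total = sum(pop.values())
    per_mut: dict[tuple[int, str], int] = {}
    for genotype, count in pop.items():
        for pos, alt in genotype:
            per_mut[(pos, alt)] = per_mut.get((pos, alt), 0) + count
    rows = []
    for (pos, alt), n in sorted(per_mut.items()):
        effects = cache.aa_effects(frozenset([(pos, alt)]))
        rows.append(
            {
                "mutation": mutation_label(pos, alt, dna),
                "aa_effect": effects[0] if effects else "synonymous",
                "frequency": n / total,
            }
        )
    return pd.DataFrame(rows, columns=["mutation", "aa_effect", "frequency"])


def run_trial(
    config: EvolutionConfig,
    seed: int | None = None,
    initial_population: dict[Genotype, int] | None = None,
) -> EvolutionTrajectory:
    """Run one directed-evolution trial and record per-round frequencies.

    The trajectory holds post-amplification mutation frequencies for rounds
    1..rounds; dominant calls apply ``consensus_threshold`` per round.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    cache = _FitnessCache(config)
    pop = dict(initial_population) if initial_population else {WT_GENOTYPE: config.founders}
    frames = []
    for rnd in range(1, config.rounds + 1):
        pop = advance_round(pop, config, rng, cache)
        freqs = _mutation_frequencies(pop, cache, config.genome.dna_seq)
        freqs.insert(0, "round", rnd)
        frames.append(freqs)
        pop = _bottleneck(pop, config.founders, rng)
    frames = [f for f in frames if not f.empty]
    table = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["round", "mutation", "aa_effect", "frequency"])
    )
    traj = EvolutionTrajectory(table=table, seed=seed)
    calls = call_dominant(traj, config.consensus_threshold)
    traj.fixation_round = dict(calls)
    for mut, rnd in calls:
        for r in range(rnd, config.rounds + 1):
            if (
                (table["round"] == r)
                & (table["mutation"] == mut)
                & (table["frequency"] > config.consensus_threshold)
            ).any():
                traj.dominant_calls.setdefault(r, []).append(mut)
    return traj


def call_dominant(
    trajectory: EvolutionTrajectory, threshold: float
) -> list[tuple[str, int]]:
    """Mutations whose frequency first exceeds ``threshold`` (strictly).

    Returns ``(mutation, fixation_round)`` pairs ordered by fixation round —
    what a per-round Sanger consensus of the population would reveal.
    """
    table = trajectory.table
    hits = table.loc[table["frequency"] > threshold]
    if hits.empty:
        return []
    first = hits.groupby("mutation")["round"].min()
    return sorted(first.items(), key=lambda kv: (kv[1], kv[0]))


def run_campaign(
    config: EvolutionConfig, n_trials: int, seeds: list[int] | None = None
) -> pd.DataFrame:
    """Independent trials; one row per (trial, dominant mutation).

    The per-site convergence statistic (how many trials fixed a mutation at
    each residue) is obtained with :func:`summarize_campaign`.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if seeds is None:
        seeds = [config.seed + i for i in range(n_trials)]
    if len(seeds) != n_trials:
        raise ValueError("need one seed per trial")
    cache = _FitnessCache(config)
    rows = []
    for trial, seed in enumerate(seeds):
        traj = run_trial(config, seed=seed)
        calls = call_dominant(traj, config.consensus_threshold)
        if not calls:
            rows.append({"trial": trial, "mutation": "", "aa_effect": "",
                         "fixation_round": -1})
        for mut, rnd in calls:
            pos = int("".join(ch for ch in mut if ch.isdigit())) - 1
            effects = cache.aa_effects(frozenset([(pos, mut[-1])]))
            rows.append(
                {
                    "trial": trial,
                    "mutation": mut,
                    "aa_effect": effects[0] if effects else "synonymous",
                    "fixation_round": rnd,
                }
            )
    return pd.DataFrame(rows, columns=["trial", "mutation", "aa_effect", "fixation_round"])


def summarize_campaign(campaign: pd.DataFrame) -> pd.DataFrame:
    """Per amino-acid site: number of trials whose dominant calls hit it."""
    called = campaign.loc[campaign["mutation"] != ""].copy()
    if called.empty:
        return pd.DataFrame(columns=["site", "n_trials", "mutations"])
    called["site"] = [
        "".join(ch for ch in eff if ch.isdigit()) if eff != "synonymous" else "syn"
        for eff in called["aa_effect"]
    ]
    out = (
        called.groupby("site")
        .agg(
            n_trials=("trial", "nunique"),
            mutations=("aa_effect", lambda s: ",".join(sorted(set(s)))),
        )
        .reset_index()
        .sort_values("n_trials", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    return out
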