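"""Coalescent simulation of single-founder polyploidization scenarios.

The species is modelled as one panmictic diploid population per subgenome
(the two subgenomes of an allotetraploid do not recombine with each other,
so one subgenome suffices for per-base statistics) founded by a single
hybrid individual T years ago.  Forward in time: a founder of size 1 grows
exponentially to the final effective size over 200 generations, then stays
constant, optionally with a bottleneck 1,000 years ago recovering to the
final size, or a recent expansion to Ne = 500,000 starting ~0.4 kya when
mass cultivation began.  The founder contributes zero standing diversity:
lineages uncoalesced at the founding time coalesce there (ancestral size 1)
and no mutations are placed on branch segments older than the founding
time, so every polymorphism postdates the polyploidization event.

Mutations are Poisson at rate μ per base per generation; everything is
deterministic given (seed, replicate index).
"""

from __future__ import annotations

import dataclasses
import logging
import math
from typing import Iterable, Sequence

import msprime
import numpy as np
import pandas as pd
import tskit

logger = logging.getLogger(__name__)

MU_LOW = 6.5e-10
MU_HIGH = 3.25e-8


@dataclasses.dataclass(frozen=True)
class Bottleneck:
    time_years: float = 1000.0
    size_fraction: float = 0.01


@dataclasses.dataclass(frozen=True)
class Expansion:
    """Recent cultivation-driven expansion: growth from the base size
    beginning ``time_years`` ago to ``ne_expanded`` at present.  The default
    mode grows exponentially over that period; ``instantaneous`` jumps to
    the expanded size at ``time_years``."""

    time_years: float = 400.0
    ne_expanded: int = 500_000
    mode: str = "exponential"

    def __post_init__(self) -> None:
        if self.mode not in ("exponential", "instantaneous"):
            raise ValueError("mode must be 'exponential' or 'instantaneous'")


@dataclasses.dataclass(frozen=True)
class DemographicModel:
    founding_time_years: int = 10_000
    ne_final: int = 10_000
    generations_per_year: float = 0.2
    growth_generations: int = 200
    bottleneck: Bottleneck | None = None
    expansion: Expansion | None = None
    mu: float = MU_HIGH
    recomb_rate: float = 1e-8
    sample_n: int = 700  # diploid individuals
    seq_length: int = 5_000_000
    seed: int = 1

    def __post_init__(self) -> None:
        if self.founding_time_years * self.generations_per_year <= self.growth_generations:
            raise ValueError("founding time (in generations) must exceed the growth phase")
        for rate in (self.mu, self.recomb_rate):
            if rate < 0:
                raise ValueError("rates must be >= 0")
        if self.sample_n > self.ne_final:
            raise ValueError("sample_n must not exceed ne_final")

    @property
    def founding_time_generations(self) -> float:
        return self.founding_time_years * self.generations_per_year

    @property
    def model_id(self) -> str:
        parts = [f"T{self.founding_time_years // 1000}ky", f"Ne{self.ne_final // 1000}k"]
        if self.bottleneck is not None:
            parts.append("bottleneck")
        if self.expansion is not None:
            parts.append("expansion")
        return "_".join(parts)


@dataclasses.dataclass
class SimulationSummary:
    model_id: str
    replicates: int
    pi_mean: float
    pi_se: float
    private_fraction_mean: float
    private_fraction_se: float
    segregating_sites_mean: float


def build_scenarios(
    founding_times: Sequence[int] = (10_000, 20_000),
    ne_finals: Sequence[int] = (10_000, 50_000),
    with_bottleneck: bool = False,
    with_expansion: bool = False,
    expansion_base: tuple[int, int] = (10_000, 50_000),
    seed: int = 1,
    **common,
) -> list[DemographicModel]:
    """The default scenario grid: {T} x {Ne} with constant size after growth
    (four base models), plus optional bottleneck variants of each and the
    single recent-expansion variant of the (10 ky, Ne 10k) base.  Duplicates
    are removed by model id."""
    if not founding_times or not ne_finals:
        raise ValueError("scenario grid must be non-empty")
    models: list[DemographicModel] = []
    for T in founding_times:
        for ne in ne_finals:
            models.append(DemographicModel(founding_time_years=T, ne_final=ne,
                                           seed=seed, **common))
            if with_bottleneck:
                models.append(
                    DemographicModel(founding_time_years=T, ne_final=ne,
                                     bottleneck=Bottleneck(), seed=seed, **common)
                )
    if with_expansion:
        T, ne = expansion_base
        models.append(
            DemographicModel(founding_time_years=T, ne_final=ne,
                             expansion=Expansion(), seed=seed, **common)
        )
    seen: dict[str, DemographicModel] = {}
    for m in models:
        seen.setdefault(m.model_id, m)
    return list(seen.values())


def _demography(model: DemographicModel) -> tuple[msprime.Demography, float]:
    T_gen = model.founding_time_generations
    g = model.generations_per_year
    growth_start = T_gen - model.growth_generations  # backward time
    # exponential decline (backwards) from ne_final to 1 over the growth phase
    alpha = math.log(model.ne_final) / model.growth_generations

    dem = msprime.Demography()
    events: list[tuple[float, dict]] = []
    if model.expansion is not None:
        exp = model.expansion
        t_exp = exp.time_years * g
        if exp.mode == "exponential":
            gamma = math.log(exp.ne_expanded / model.ne_final) / t_exp
            dem.add_population(name="pop", initial_size=exp.ne_expanded, growth_rate=gamma)
        else:
            dem.add_population(name="pop", initial_size=exp.ne_expanded)
        events.append((t_exp, {"initial_size": model.ne_final, "growth_rate": 0}))
    else:
        dem.add_population(name="pop", initial_size=model.ne_final)
    if model.bottleneck is not None:
        t_b = model.bottleneck.time_years * g
        beta = math.log(1.0 / model.bottleneck.size_fraction) / t_b
        # recovery looks, backwards, like exponential shrinkage into the bottleneck
        events.append((0.0, {"initial_size": model.ne_final, "growth_rate": beta}))
        events.append((t_b, {"initial_size": model.ne_final, "growth_rate": 0}))
    events.append((growth_start, {"initial_size": model.ne_final, "growth_rate": alpha}))
    events.append((T_gen, {"initial_size": 1.0, "growth_rate": 0}))
    for time, kwargs in sorted(events, key=lambda e: e[0]):
        dem.add_population_parameters_change(time=time, population="pop", **kwargs)
    return dem, T_gen


def simulate_model(
    model: DemographicModel,
    replicates: int = 10,
) -> list[tskit.TreeSequence]:
    """Simulate ``replicates`` independent tree sequences with mutations,
    honouring the zero-founder-diversity contract (no mutation older than
    the founding time)."""
    if model.seq_length < 1e5:
        raise ValueError("seq_length must be >= 1e5")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    dem, T_gen = _demography(model)
    rng = np.random.SeedSequence(model.seed)
    seeds = [int(s.generate_state(1)[0] % (2**31 - 1)) + 1 for s in rng.spawn(2 * replicates)]
    out = []
    for i in range(replicates):
        ts = msprime.sim_ancestry(
            samples=model.sample_n,
            demography=dem,
            sequence_length=model.seq_length,
            recombination_rate=model.recomb_rate,
            random_seed=seeds[2 * i],
        )
        ts = msprime.sim_mutations(
            ts,
            rate=model.mu,
            random_seed=seeds[2 * i + 1],
            model=msprime.BinaryMutationModel(),
            discrete_genome=False,
            end_time=T_gen,
        )
        out.append(ts)
    return out


def _private_and_segregating(ts: tskit.TreeSequence) -> tuple[int, int]:
    """Count segregating sites and sites whose derived allele is carried by
    exactly one diploid individual (one or two copies)."""
    individual_of = ts.nodes_individual
    n_samples = ts.num_samples
    private = 0
    segregating = 0
    for tree in ts.trees():
        for site in tree.sites():
            if len(site.mutations) != 1:
                # multiple hits at one continuous-genome position: vanishingly
                # rare; count as segregating, never private
                if site.mutations:
                    segregating += 1
                continue
            count = tree.num_samples(site.mutations[0].node)
            if count == 0 or count == n_samples:
                continue
            segregating += 1
            if count == 1:
                private += 1
            elif count == 2:
                a, b = tree.samples(site.mutations[0].node)
                if individual_of[a] == individual_of[b]:
                    private += 1
    return private, segregating


def summarize_simulation(
    replicates: Iterable[tskit.TreeSequence],
    model_id: str = "",
) -> SimulationSummary:
    """π (mean pairwise difference per base over the sampled haplotypes),
    individual-private fraction of segregating sites, and S, with means and
    standard errors over replicates.  Replicates without segregating sites
    are excluded from the private-fraction mean and logged."""
    pis, fractions, seg_counts = [], [], []
    for ts in replicates:
        pis.append(float(ts.diversity(span_normalise=True)))
        private, segregating = _private_and_segregating(ts)
        seg_counts.append(segregating)
        if segregating == 0:
            logger.info("replicate with zero segregating sites excluded from private fraction")
            continue
        fractions.append(private / segregating)
    if not pis:
        raise ValueError("need at least one replicate")

    def _mean_se(values: list[float]) -> tuple[float, float]:
        arr = np.asarray(values, dtype=float)
        if arr.size == 0:
            return float("nan"), float("nan")
        se = float(arr.std(ddof=1) / np.sqrt(arr.size)) if arr.size > 1 else 0.0
        return float(arr.mean()), se

    pi_mean, pi_se = _mean_se(pis)
    pf_mean, pf_se = _mean_se(fractions)
    return SimulationSummary(
        model_id=model_id,
        replicates=len(pis),
        pi_mean=pi_mean,
        pi_se=pi_se,
        private_fraction_mean=pf_mean,
        private_fraction_se=pf_se,
        segregating_sites_mean=float(np.mean(seg_counts)),
    )


def run_scenario(model: DemographicModel, replicates: int = 10) -> SimulationSummary:
    return summarize_simulation(simulate_model(model, replicates), model.model_id)


def scenario_table(
    models: Sequence[DemographicModel],
    mutation_rates: Sequence[float] = (MU_LOW, MU_HIGH),
    replicates: int = 10,
) -> pd.DataFrame:
    """One row per (model, μ) with π, private fraction and S summaries, plus
    min/max range rows over the base (no-variant) models per μ."""
    rows = []
    for mu in mutation_rates:
        for model in models:
            m = dataclasses.replace(model, mu=mu)
            summary = run_scenario(m, replicates)
            rows.append(
                {
                    "model_id": m.model_id,
                    "mu": mu,
                    "row_type": "scenario",
                    "pi_mean": summary.pi_mean,
                    "pi_se": summary.pi_se,
                    "private_fraction_mean": summary.private_fraction_mean,
                    "private_fraction_se": summary.private_fraction_se,
                    "segregating_sites_mean": summary.segregating_sites_mean,
                }
            )
    table = pd.DataFrame(rows)
    base_ids = {
        m.model_id for m in models if m.bottleneck is None and m.expansion is None
    }
    for mu in mutation_rates:
        sub = table[(table["mu"] == mu) & table["model_id"].isin(base_ids)]
        if sub.empty:
            continue
        rows.append(
            {
                "model_id": "range_over_base_models",
                "mu": mu,
                "row_type": "range",
                "pi_min": float(sub["pi_mean"].min()),
                "pi_max": float(sub["pi_mean"].max()),
                "private_fraction_min": float(sub["private_fraction_mean"].min()),
                "private_fraction_max": float(sub["private_fraction_mean"].max()),
            }
        )
    return pd.DataFrame(rows)
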