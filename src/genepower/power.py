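"""Replicated power estimation over factorial simulation grids.

A :class:`SimulationSetting` fixes the disease architecture (number of causal
SNPs, relative risk, MAFs), the sample size, and the LD layout of the SNP
set.  For each setting one large population of genotypes is simulated at HWE
and assigned disease status; replicated case-control samples are then drawn
from that population and each gene-based test applied at level alpha.  Power
is the rejection fraction over replicates (non-convergent logistic fits are
excluded from the denominator and counted separately).

Three grid constructors reproduce the study designs:

* :func:`build_nold_grid` -- 288 settings, all SNPs independent;
* :func:`build_causal_ld_grid` -- 96 settings with causal-anchored blocks
  (192 with the tag-SNP-only duplicates);
* :func:`build_noncausal_ld_grid` -- exchangeable LD among non-causal SNPs
  in one or two blocks at r = 0.5 / 0.9.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import product

import numpy as np
import pandas as pd

from ._rng import spawn_rng
from .errors import ParameterError, SamplingError
from .genotypes import (GenotypeMatrix, simulate_causal_anchored_block,
                        simulate_exchangeable_block, simulate_independent)
from .phenotypes import (DiseaseModel, sample_case_control,
                         simulate_disease_status)
from .settests import (METHODS, _vegas_null_chi2, gates, lr_pc_test, lr_test,
                       pairwise_ld, trend_statistics, vegas)

__all__ = [
    "SimulationSetting",
    "POWER_TABLE_COLUMNS",
    "run_setting",
    "run_pool_setting",
    "run_grid",
    "build_nold_grid",
    "build_causal_ld_grid",
    "build_noncausal_ld_grid",
]

# factorial domains of the study grids
CAUSAL_COUNTS = (1, 2, 4, 8)
NONCAUSAL_COUNTS = (2, 4, 8, 32)
RELATIVE_RISKS = (1.25, 2.0)
SAMPLE_SIZES = (2000, 4000)
MAFS = (0.05, 0.30)
LD_LEVELS = (0.5, 0.9)
GRID_ARCHITECTURE = 8  # causal SNPs generating disease in every study grid

POPULATION_MULTIPLIER = 20
CASE_HEADROOM = 1.5


@dataclass(frozen=True)
class SimulationSetting:
    """One cell of a factorial power study.

    ``n_causal`` is the number of causal SNPs *included in the analyzed set*.
    ``n_causal_model`` is the number of causal SNPs in the generating disease
    architecture; it defaults to ``n_causal`` (every causal SNP measured) but
    the study grids pin it at 8 so that varying ``n_causal`` changes only
    which SNPs the test sees, not the disease being simulated.  Each
    architecture SNP carries unique prevalence 0.10 / n_causal_model.
    """

    setting_id: str
    n_causal: int
    n_noncausal: int
    rr: float
    n_total: int
    maf_causal: float
    maf_noncausal: float
    ld_kind: str = "independent"  # independent | exchangeable | causal_anchored
    block_rs: tuple = ()  # per-block correlation (exchangeable) or (r,) anchored
    analyze_mask: str = "all"  # all | noncausal_only
    n_causal_model: int | None = None
    replicates: int = 500
    alpha: float = 0.05

    def __post_init__(self):
        if self.replicates < 1:
            raise ParameterError("replicates must be >= 1")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.analyze_mask not in ("all", "noncausal_only"):
            raise ParameterError("analyze_mask must be 'all' or 'noncausal_only'")
        if self.ld_kind not in ("independent", "exchangeable", "causal_anchored"):
            raise ParameterError(f"unknown ld_kind {self.ld_kind!r}")
        if self.n_causal_model is not None and self.n_causal_model < self.n_causal:
            raise ParameterError(
                "the disease architecture cannot have fewer causal SNPs than "
                "the analyzed set includes")

    @property
    def architecture_size(self) -> int:
        """Causal SNPs in the generating model (>= those analyzed)."""
        return self.n_causal_model if self.n_causal_model is not None else self.n_causal

    @property
    def ld_level(self) -> float:
        """Fraction of LD blocks at the high (r=0.9) level; 0 with no LD."""
        if not self.block_rs:
            return 0.0
        return float(np.mean([r == 0.9 for r in self.block_rs]))

    @property
    def n_blocks(self) -> int:
        return len(self.block_rs)


def _even_split(total: int, parts: int) -> list:
    base, rem = divmod(total, parts)
    return [base + (1 if k < rem else 0) for k in range(parts)]


def build_population(setting: SimulationSetting, n_pop: int, rng):
    """Population genotypes for one setting.

    Column layout: the ``architecture_size`` causal SNPs first (the analyzed
    ones in columns 0..n_causal-1, unmeasured architecture SNPs after them),
    then the ``n_noncausal`` non-causal SNPs.  LD blocks only ever involve
    SNPs of the analyzed set; unmeasured causal SNPs are independent.
    """
    na, nc, nn = setting.architecture_size, setting.n_causal, setting.n_noncausal
    mafs = np.concatenate([
        np.full(na, setting.maf_causal), np.full(nn, setting.maf_noncausal)
    ])
    if setting.ld_kind == "independent":
        return simulate_independent(n_pop, mafs, rng)
    if setting.ld_kind == "exchangeable":
        parts = [simulate_independent(n_pop, np.full(na, setting.maf_causal), rng).values]
        sizes = _even_split(nn, len(setting.block_rs))
        for size, r in zip(sizes, setting.block_rs):
            parts.append(simulate_exchangeable_block(
                n_pop, setting.maf_noncausal, size, r, rng).values)
        return GenotypeMatrix(np.concatenate(parts, axis=1), mafs)
    # causal_anchored: one block per analyzed causal SNP, members split evenly
    (r,) = setting.block_rs
    if not math.isclose(setting.maf_causal, setting.maf_noncausal):
        raise ParameterError(
            "causal-anchored blocks use a single MAF for causal and non-causal SNPs")
    sizes = _even_split(nn, nc)
    anchors, members = [], []
    for size in sizes:
        block = simulate_causal_anchored_block(n_pop, setting.maf_causal, size, r, rng)
        anchors.append(block.values[:, :1])
        members.append(block.values[:, 1:])
    if na > nc:  # unmeasured architecture SNPs, independent of the blocks
        anchors.append(simulate_independent(
            n_pop, np.full(na - nc, setting.maf_causal), rng).values)
    values = np.concatenate(anchors + members, axis=1)
    return GenotypeMatrix(values, mafs)


def _population_size(setting: SimulationSetting, model: DiseaseModel) -> int:
    need_cases = math.ceil(CASE_HEADROOM * (setting.n_total // 2)
                           / model.expected_prevalence())
    return max(POPULATION_MULTIPLIER * setting.n_total, need_cases)


def _apply_methods(values, status, alpha, methods, vegas_sims, vegas_rng):
    """p-value and convergence flag per requested method on one sample."""
    stats_, pvals = (np.array([]), np.array([])) if values.shape[1] == 0 \
        else trend_statistics(values, status)
    ld = pairwise_ld(values) if values.shape[1] else None
    out = {}
    need_vegas = "VEGAS-SUM" in methods or "VEGAS-MAX" in methods
    null_chi2 = None
    if need_vegas and values.shape[1]:
        null_chi2 = _vegas_null_chi2(ld, vegas_sims, vegas_rng)
    for method in methods:
        if values.shape[1] == 0:
            out[method] = (1.0, True)
            continue
        if method == "GATES":
            res = gates(pvals, ld)
        elif method == "VEGAS-SUM":
            res = vegas(stats_, ld, "sum", null_chi2=null_chi2)
        elif method == "VEGAS-MAX":
            res = vegas(stats_, ld, "max", null_chi2=null_chi2)
        elif method == "LR":
            res = lr_test(values, status)
        elif method == "LR-PC":
            res = lr_pc_test(values, status)
        else:
            raise ParameterError(f"unknown method {method!r}")
        out[method] = (res.p_value, res.details.get("converged", True))
    return out


def _replicate_rejections(analyzed, status, n_cases, n_controls, reps, alpha,
                          methods, vegas_sims, seed, label):
    """Replicated case-control draws from one population; rejection counts."""
    rejections = {m: 0 for m in methods}
    failures = {m: 0 for m in methods}
    for rep in range(reps):
        sample_rng = spawn_rng(seed, "sampling", label, rep)
        vegas_rng = spawn_rng(seed, "vegas", label, rep)
        sample, y = sample_case_control(analyzed, status, n_cases, n_controls,
                                        sample_rng)
        results = _apply_methods(sample.values, y.status, alpha, methods,
                                 vegas_sims, vegas_rng)
        for method, (p, converged) in results.items():
            if not converged:
                failures[method] += 1
            elif p <= alpha:
                rejections[method] += 1
    return rejections, failures


def run_pool_setting(pool, included, rr: float, n_total: int,
                     replicates: int = 500, seed: int = 0, alpha: float = 0.05,
                     methods=METHODS, vegas_sims: int = 1000) -> dict:
    """Power of each method on a haplotype-pool population.

    Disease is generated by the pool's designated causal SNPs (unique
    prevalence 0.10 / n_causal each, relative risk ``rr`` per SNP); the test
    sees only the ``included`` SNP indices, e.g. a window or LD selection.
    Returns method -> estimated power.
    """
    from .genotypes import sample_from_pool

    included = np.asarray(included, dtype=int)
    n_cases = n_controls = n_total // 2
    mafs = pool.implied_mafs()
    model = DiseaseModel(pool.causal_indices, mafs[pool.causal_indices], rr)
    n_pop = max(POPULATION_MULTIPLIER * n_total,
                math.ceil(CASE_HEADROOM * n_cases / model.expected_prevalence()))
    population = sample_from_pool(pool, n_pop, spawn_rng(seed, "pool-genotypes"))
    status = simulate_disease_status(population, model,
                                     spawn_rng(seed, "pool-disease"))
    rejections, failures = _replicate_rejections(
        population.subset_snps(included), status, n_cases, n_controls,
        replicates, alpha, methods, vegas_sims, seed, "pool")
    return {
        m: rejections[m] / (replicates - failures[m])
        if replicates > failures[m] else 0.0
        for m in methods
    }


def run_setting(setting: SimulationSetting, methods=METHODS, seed: int = 0,
                replicates: int | None = None, vegas_sims: int = 1000) -> list:
    """Estimate power for each method on one setting; returns row dicts."""
    reps = replicates if replicates is not None else setting.replicates
    if reps < 1:
        raise ParameterError("replicates must be >= 1")
    na = setting.architecture_size
    model = DiseaseModel(
        causal_indices=np.arange(na),
        causal_mafs=np.full(na, setting.maf_causal),
        gamma=setting.rr,
    )
    pop_rng = spawn_rng(seed, "genotypes", setting.setting_id)
    disease_rng = spawn_rng(seed, "disease", setting.setting_id)

    n_pop = _population_size(setting, model)
    n_cases = n_controls = setting.n_total // 2
    for attempt in range(3):
        population = build_population(setting, n_pop, pop_rng)
        status = simulate_disease_status(population, model, disease_rng)
        if status.n_cases >= n_cases and status.n - status.n_cases >= n_controls:
            break
        n_pop *= 2
    else:
        raise SamplingError(
            f"could not realize {n_cases} cases even with population {n_pop}")

    noncausal_cols = np.arange(na, na + setting.n_noncausal)
    if setting.analyze_mask == "noncausal_only":
        analyzed = population.subset_snps(noncausal_cols)
    else:
        analyzed = population.subset_snps(
            np.concatenate([np.arange(setting.n_causal), noncausal_cols]))

    rejections, failures = _replicate_rejections(
        analyzed, status, n_cases, n_controls, reps, setting.alpha, methods,
        vegas_sims, seed, setting.setting_id)

    rows = []
    for method in methods:
        effective = reps - failures[method]
        power = rejections[method] / effective if effective else 0.0
        rows.append({
            "setting_id": setting.setting_id,
            "n_causal": setting.n_causal,
            "n_noncausal": setting.n_noncausal,
            "rr": setting.rr,
            "n_total": setting.n_total,
            "maf_causal": setting.maf_causal,
            "maf_noncausal": setting.maf_noncausal,
            "ld_kind": setting.ld_kind,
            "n_blocks": setting.n_blocks,
            "ld_level": setting.ld_level,
            "analyze_mask": setting.analyze_mask,
            "alpha": setting.alpha,
            "replicates": effective,
            "method": method,
            "power": power,
            "mc_se": math.sqrt(power * (1 - power) / effective) if effective else float("nan"),
            "n_failed": failures[method],
        })
    return rows


POWER_TABLE_COLUMNS = [
    "setting_id", "n_causal", "n_noncausal", "rr", "n_total", "maf_causal",
    "maf_noncausal", "ld_kind", "n_blocks", "ld_level", "analyze_mask",
    "alpha", "replicates", "method", "power", "mc_se", "n_failed",
]


def run_grid(grid, methods=METHODS, replicates: int | None = None,
             base_seed: int = 0, workers: int = 1,
             vegas_sims: int = 1000) -> pd.DataFrame:
    """Run every setting of a grid; deterministic for a given base seed
    regardless of worker count (per-setting seeds derive from the setting id).
    """
    if replicates is not None and replicates < 1:
        raise ParameterError("replicates override must be >= 1")

    def one(setting):
        return run_setting(setting, methods=methods, seed=base_seed,
                           replicates=replicates, vegas_sims=vegas_sims)

    if workers > 1:
        from joblib import Parallel, delayed

        chunks = Parallel(n_jobs=workers)(delayed(one)(s) for s in grid)
    else:
        chunks = [one(s) for s in grid]
    rows = [row for chunk in chunks for row in chunk]
    return pd.DataFrame(rows, columns=POWER_TABLE_COLUMNS)


# ---------------------------------------------------------------------------
# Grid constructors
# ---------------------------------------------------------------------------

def _causal_combinations():
    """The 32 causal-side parameter combinations shared by all grids."""
    return list(product(CAUSAL_COUNTS, RELATIVE_RISKS, SAMPLE_SIZES, MAFS))


def build_nold_grid(replicates: int = 500, alpha: float = 0.05) -> list:
    """288 settings: 32 causal combinations x 9 non-causal options (none, or
    2/4/8/32 SNPs at MAF 5% or 30%), all SNPs independent."""
    noncausal_options = [(0, 0.0)] + list(product(NONCAUSAL_COUNTS, MAFS))
    grid = []
    for idx, ((nc, rr, n, maf_c), (nn, maf_n)) in enumerate(
            product(_causal_combinations(), noncausal_options)):
        grid.append(SimulationSetting(
            setting_id=f"nold-{idx:04d}", n_causal=nc, n_noncausal=nn, rr=rr,
            n_total=n, maf_causal=maf_c, maf_noncausal=maf_n,
            ld_kind="independent", n_causal_model=GRID_ARCHITECTURE,
            replicates=replicates, alpha=alpha))
    assert len(grid) == 288
    return grid


def build_causal_ld_grid(include_tag_only: bool = False, replicates: int = 500,
                         alpha: float = 0.05) -> list:
    """96 settings with causal-anchored LD blocks: 3 causal counts x 2
    non-causal counts x 2 RR x 2 n x 2 MAF x 2 LD levels; a single MAF is
    shared by causal and non-causal SNPs.  With ``include_tag_only`` each
    setting is duplicated with only the non-causal (tag) SNPs analyzed (192).
    """
    grid = []
    idx = 0
    for nc, nn, rr, n, maf, r in product((1, 2, 4), (4, 8), RELATIVE_RISKS,
                                         SAMPLE_SIZES, MAFS, LD_LEVELS):
        grid.append(SimulationSetting(
            setting_id=f"cld-{idx:04d}", n_causal=nc, n_noncausal=nn, rr=rr,
            n_total=n, maf_causal=maf, maf_noncausal=maf,
            ld_kind="causal_anchored", block_rs=(r,),
            n_causal_model=GRID_ARCHITECTURE, replicates=replicates,
            alpha=alpha))
        idx += 1
    assert len(grid) == 96
    if include_tag_only:
        grid = grid + [
            replace(s, setting_id=s.setting_id + "-tag", analyze_mask="noncausal_only")
            for s in grid
        ]
        assert len(grid) == 192
    return grid


def build_noncausal_ld_grid(replicates: int = 500, alpha: float = 0.05) -> list:
    """Exchangeable LD among non-causal SNPs, causal SNPs independent.

    Enumeration: the 32 causal combinations are crossed with non-causal
    configurations where 2/4/8/32 non-causal SNPs at MAF 5% or 30% sit either
    all in one block (r = 0.5 or 0.9) or, for counts >= 4, evenly split into
    two blocks (low/low, high/high or high/low) -- blocks need at least two
    members, so the count-2 settings only admit the one-block layouts.  That
    gives 32 x (8x2 + 6x3) = 1088 settings, a count this constructor asserts
    for itself.
    """
    block_layouts = [(0.5,), (0.9,), (0.5, 0.5), (0.9, 0.9), (0.9, 0.5)]
    grid = []
    idx = 0
    for (nc, rr, n, maf_c), (nn, maf_n), layout in product(
            _causal_combinations(), product(NONCAUSAL_COUNTS, MAFS), block_layouts):
        if len(layout) == 2 and nn < 4:
            continue  # two blocks need >= 2 members each
        grid.append(SimulationSetting(
            setting_id=f"ncld-{idx:04d}", n_causal=nc, n_noncausal=nn, rr=rr,
            n_total=n, maf_causal=maf_c, maf_noncausal=maf_n,
            ld_kind="exchangeable", block_rs=layout,
            n_causal_model=GRID_ARCHITECTURE, replicates=replicates,
            alpha=alpha))
        idx += 1
    assert len(grid) == 1088
    return grid
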