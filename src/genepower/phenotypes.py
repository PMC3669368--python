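"""Bernoulli disease model and case-control sampling.

Each causal SNP carries its own "unique" disease prevalence
``P(D_U) = 0.10 / i`` (``i`` = number of causal SNPs), so the overall
prevalence ``1 - (1 - 0.10/i)**i`` stays close to 10% for any i.  Risk is
additive on the probability scale with relative risk ``gamma`` per copy of
the risk allele:

    P(D|G=0) = P(D_U) / [(1-m)^2 + 2*gamma*m*(1-m) + (2*gamma-1)*m^2]
    P(D|G=1) = gamma * P(D|G=0)
    P(D|G=2) = (2*gamma - 1) * P(D|G=0)

The denominator is the HWE-weighted normalizer, so the genotype-averaged
disease probability equals P(D_U) exactly.  An individual is a case if any
causal SNP's Bernoulli draw comes up "diseased".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._rng import as_generator
from .errors import FeasibilityError, ParameterError, SamplingError
from .genotypes import GenotypeMatrix

__all__ = [
    "DiseaseModel",
    "PhenotypeVector",
    "conditional_disease_probs",
    "simulate_disease_status",
    "sample_case_control",
    "read_phenotype_tsv",
    "write_phenotype_tsv",
]

TOTAL_UNIQUE_PREVALENCE = 0.10


def conditional_disease_probs(p_du: float, m: float, gamma: float) -> tuple:
    """(P(D|G=0), P(D|G=1), P(D|G=2)) for one causal SNP."""
    if not 0.0 < p_du < 1.0:
        raise ParameterError("p_du must lie in (0, 1)")
    if not 0.0 < m <= 0.5:
        raise ParameterError("MAF must lie in (0, 0.5]")
    if gamma < 1.0:
        raise ParameterError("relative risk gamma must be >= 1")
    denom = (1 - m) ** 2 + 2 * gamma * m * (1 - m) + (2 * gamma - 1) * m**2
    p0 = p_du / denom
    probs = (p0, gamma * p0, (2 * gamma - 1) * p0)
    if probs[2] > 1.0:
        raise FeasibilityError(
            f"P(D|G=2) = {probs[2]:.4f} > 1 for p_du={p_du}, m={m}, gamma={gamma}"
        )
    return probs


@dataclass
class DiseaseModel:
    """Disease architecture: which SNPs are causal and how strongly.

    ``p_du`` defaults to 0.10 / n_causal so overall prevalence is ~10%.
    """

    causal_indices: np.ndarray
    causal_mafs: np.ndarray
    gamma: float
    p_du: float | None = None

    def __post_init__(self):
        self.causal_indices = np.atleast_1d(np.asarray(self.causal_indices, dtype=int))
        self.causal_mafs = np.atleast_1d(np.asarray(self.causal_mafs, dtype=float))
        if self.causal_indices.shape[0] != self.causal_mafs.shape[0]:
            raise ParameterError("one MAF per causal SNP required")
        if self.p_du is None:
            self.p_du = TOTAL_UNIQUE_PREVALENCE / self.n_causal
        # validate every per-SNP conditional probability up front
        for m in self.causal_mafs:
            conditional_disease_probs(self.p_du, m, self.gamma)

    @property
    def n_causal(self) -> int:
        return self.causal_indices.shape[0]

    def expected_prevalence(self) -> float:
        return 1.0 - (1.0 - self.p_du) ** self.n_causal

    def genotype_risk_table(self) -> np.ndarray:
        """(n_causal, 3) array of P(D_U | G=g) per causal SNP."""
        return np.array([
            conditional_disease_probs(self.p_du, m, self.gamma)
            for m in self.causal_mafs
        ])


@dataclass
class PhenotypeVector:
    """Binary case/control status (1 = case)."""

    status: np.ndarray

    def __post_init__(self):
        self.status = np.asarray(self.status, dtype=np.int8)
        if self.status.size and not np.isin(self.status, (0, 1)).all():
            raise ParameterError("status entries must be 0 or 1")

    @property
    def n(self) -> int:
        return self.status.shape[0]

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())


def simulate_disease_status(genotypes: GenotypeMatrix, model: DiseaseModel,
                            seed=None) -> PhenotypeVector:
    """One Bernoulli draw per (individual, causal SNP); case = any draw hits.

    Uniform draws are laid out individual-major / causal-SNP-minor for
    reproducibility under a fixed seed.
    """
    if model.causal_indices.size and model.causal_indices.max() >= genotypes.n_snps:
        raise ParameterError("causal index out of range for the genotype matrix")
    rng = as_generator(seed)
    risk = model.genotype_risk_table()  # (i, 3)
    g = genotypes.values[:, model.causal_indices]  # (n, i)
    probs = np.take_along_axis(risk.T[None, :, :], g[:, None, :], axis=1)[:, 0, :]
    u = rng.random(g.shape)
    status = (u < probs).any(axis=1)
    return PhenotypeVector(status.astype(np.int8))


def sample_case_control(genotypes: GenotypeMatrix, status: PhenotypeVector,
                        n_cases: int, n_controls: int, seed=None):
    """Uniform without-replacement subsample within each status stratum.

    Returns (GenotypeMatrix, PhenotypeVector) ordered cases-then-controls.
    """
    rng = as_generator(seed)
    case_idx = np.flatnonzero(status.status == 1)
    control_idx = np.flatnonzero(status.status == 0)
    if case_idx.size < n_cases or control_idx.size < n_controls:
        raise SamplingError(
            f"population has {case_idx.size} cases / {control_idx.size} controls, "
            f"need {n_cases} / {n_controls}; regenerate with a larger population "
            "multiplier"
        )
    chosen = np.concatenate([
        rng.choice(case_idx, n_cases, replace=False),
        rng.choice(control_idx, n_controls, replace=False),
    ])
    new_status = np.concatenate([
        np.ones(n_cases, dtype=np.int8), np.zeros(n_controls, dtype=np.int8)
    ])
    return genotypes.subset_individuals(chosen), PhenotypeVector(new_status)


def write_phenotype_tsv(pheno: PhenotypeVector, path, ids=None) -> None:
    ids = ids or [f"ind{i + 1}" for i in range(pheno.n)]
    with open(path, "w") as fh:
        fh.write("individual\tstatus\n")
        for ind, s in zip(ids, pheno.status):
            fh.write(f"{ind}\t{int(s)}\n")


def read_phenotype_tsv(path) -> PhenotypeVector:
    status = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("individual"):
            raise ParameterError(f"unexpected phenotype header in {path}")
        for line in fh:
            if line.strip():
                status.append(int(line.rstrip("\n").split("\t")[1]))
    return PhenotypeVector(np.array(status, dtype=np.int8))
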