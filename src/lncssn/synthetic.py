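"""Synthetic cohort generator.

Emulates the statistical structure the downstream analysis assumes: a
reference group of normal samples sharing a modular coexpression structure,
tumor samples in which a planted subset of lncRNAs ("drivers") has rewired
correlations to its partner genes, a negative-binomial count observation
layer, and exponential survival whose hazard depends on the planted drivers'
expression, with independent censoring.

Construction
------------
All genes live on a latent Gaussian layer that is mapped to negative-
binomial counts through a Gaussian copula (count = NB quantile of the
standard-normal CDF of the latent value), so pairwise Pearson structure is
the controlled quantity.  Protein-coding genes are grouped into coexpression
modules of ``n_partners_per_driver`` genes each, every gene loading
``sqrt(baseline_corr)`` on its module factor; every lncRNA is attached to
one module the same way, so under zero perturbation drivers are exactly
exchangeable with background lncRNAs.  In tumor samples each driver's factor
loading is attenuated (or sign-flipped) so that its correlation with partner
genes shifts by ``perturbation_strength``, and its latent level is displaced
by ``driver_displacement_scale * perturbation_strength`` latent standard
deviations — the expression deviation that accompanies a lost regulatory
coupling and that makes the rewiring visible to a single added sample.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .containers import (
    ExpressionMatrix,
    CLINICAL_COLUMNS,
    LNCRNA,
    MRNA,
    REFERENCE,
    TUMOR,
)

ATTENUATE = "attenuate"
SIGN_FLIP = "sign_flip"


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults describe the standard study conditions: 50 reference samples,
    100 tumor samples, 60 lncRNAs and 200 mRNAs with three planted driver
    lncRNAs, baseline within-module correlation 0.7 and a correlation shift
    of 0.6 in tumors.  ``baseline_hazard`` is in events/day; the default
    4e-4 gives a median overall survival near 4.7 years for an average-risk
    patient, and ``censoring_rate`` 2.4e-4 yields roughly 40% censoring.
    """

    n_ref_samples: int = 50
    n_tumor_samples: int = 100
    n_lnc: int = 60
    n_mrna: int = 200
    n_perturbed_lnc: int = 3
    n_partners_per_driver: int = 20
    baseline_corr: float = 0.7
    perturbation_strength: float = 0.6
    nb_dispersion: float = 0.1
    mean_log_expression: float = 4.0
    hazard_coefficients: tuple[float, ...] = (0.7, 0.7, 0.7)
    baseline_hazard: float = 4e-4
    censoring_rate: float = 2.4e-4
    seed: int = 0
    # perturbation shape
    perturbation_mode: str = ATTENUATE
    driver_displacement_scale: float = 3.0
    # observation layer
    log_expression_sd: float = 0.5
    # optional tumor/reference mean shifts for non-driver genes (log2 scale),
    # used to give the differential-expression stage a realistic substrate
    background_log2fc_sd: float = 0.0

    def validate(self) -> None:
        counts = {
            "n_ref_samples": self.n_ref_samples,
            "n_tumor_samples": self.n_tumor_samples,
            "n_lnc": self.n_lnc,
            "n_mrna": self.n_mrna,
            "n_perturbed_lnc": self.n_perturbed_lnc,
            "n_partners_per_driver": self.n_partners_per_driver,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value}")
        if self.n_perturbed_lnc > self.n_lnc:
            raise ValueError("n_perturbed_lnc cannot exceed n_lnc")
        if self.n_partners_per_driver > self.n_mrna:
            raise ValueError("n_partners_per_driver cannot exceed n_mrna")
        if not 0.0 <= self.baseline_corr <= 1.0:
            raise ValueError("baseline_corr must be in [0, 1]")
        if not 0.0 <= self.perturbation_strength <= 1.0:
            raise ValueError("perturbation_strength must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censoring_rate < 0:
            raise ValueError("censoring_rate must be non-negative")
        if len(self.hazard_coefficients) != self.n_perturbed_lnc:
            raise ValueError(
                "hazard_coefficients must have one entry per perturbed lncRNA "
                f"({self.n_perturbed_lnc}), got {len(self.hazard_coefficients)}"
            )
        if self.perturbation_mode not in (ATTENUATE, SIGN_FLIP):
            raise ValueError(f"unknown perturbation_mode {self.perturbation_mode!r}")
        if self.perturbation_mode == ATTENUATE and self.baseline_corr > 0:
            a = self._perturbed_loading()
            if abs(a) > 1:
                raise ValueError(
                    "perturbation_strength too large for baseline_corr: "
                    "perturbed loading would exceed unit variance"
                )

    def _perturbed_loading(self) -> float:
        rho = self.baseline_corr
        if rho == 0:
            return 0.0
        if self.perturbation_mode == SIGN_FLIP:
            return -np.sqrt(rho)
        # attenuate so that driver-partner correlation becomes rho - strength
        return (rho - self.perturbation_strength) / np.sqrt(rho)


@dataclass
class SyntheticTruth:
    """Ground truth of a simulated cohort: which lncRNAs were perturbed."""

    driver_lnc_ids: list[str]
    partner_map: dict[str, list[str]]
    true_beta: dict[str, float]

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        return cls(**json.loads(Path(path).read_text()))


def _nb_counts(rng_latent: np.ndarray, mu: np.ndarray, dispersion: float) -> np.ndarray:
    """Map latent standard-normal values to NB counts via the copula.

    ``mu`` is broadcast against the latent matrix; the NB size parameter is
    1/dispersion so that var = mu + dispersion * mu^2.
    """
    size = 1.0 / dispersion
    p = size / (size + mu)
    u = np.clip(stats.norm.cdf(rng_latent), 1e-12, 1 - 1e-12)
    return stats.nbinom.ppf(u, size, p).astype(np.int64)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: counts, clinical table for tumor samples, truth.

    The same config (including seed) always produces identical output; all
    randomness flows through a single generator stream.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    L, M = config.n_lnc, config.n_mrna
    n_ref, n_tum = config.n_ref_samples, config.n_tumor_samples
    G = L + M
    rho = config.baseline_corr
    npart = config.n_partners_per_driver
    n_modules = max(1, M // npart)

    lnc_ids = [f"LNC{i:04d}" for i in range(L)]
    mrna_ids = [f"MRNA{i:04d}" for i in range(M)]
    gene_ids = lnc_ids + mrna_ids
    gene_info = pd.DataFrame(
        {
            "symbol": [f"LINC{i:04d}" for i in range(L)]
            + [f"GENE{i:04d}" for i in range(M)],
            "biotype": [LNCRNA] * L + [MRNA] * M,
        },
        index=pd.Index(gene_ids, name="gene_id"),
    )

    # module membership: mRNAs in consecutive blocks of a random permutation,
    # every lncRNA attached to one module
    mrna_perm = rng.permutation(M)
    mrna_module = np.full(M, -1)
    for m in range(n_modules):
        mrna_module[mrna_perm[m * npart : (m + 1) * npart]] = m
    lnc_module = rng.integers(0, n_modules, size=L)
    driver_idx = np.sort(rng.choice(L, size=config.n_perturbed_lnc, replace=False))

    a0 = np.sqrt(rho)
    b0 = np.sqrt(1.0 - rho)
    a1 = config._perturbed_loading()
    b1 = np.sqrt(max(0.0, 1.0 - a1 * a1))
    displacement = config.driver_displacement_scale * config.perturbation_strength

    def draw_latent(n: int, tumor: bool) -> np.ndarray:
        factors = rng.standard_normal((n_modules, n))
        Z = np.empty((G, n))
        eps_l = rng.standard_normal((L, n))
        Z[:L] = a0 * factors[lnc_module] + b0 * eps_l
        eps_m = rng.standard_normal((M, n))
        in_mod = mrna_module >= 0
        Z[L:][in_mod] = a0 * factors[mrna_module[in_mod]] + b0 * eps_m[in_mod]
        Z[L:][~in_mod] = eps_m[~in_mod]
        if tumor:
            for d in driver_idx:
                Z[d] = (
                    a1 * factors[lnc_module[d]]
                    + b1 * rng.standard_normal(n)
                    + displacement
                )
        return Z

    z_ref = draw_latent(n_ref, tumor=False)
    z_tum = draw_latent(n_tum, tumor=True)

    base_mu = np.exp(
        config.mean_log_expression + config.log_expression_sd * rng.standard_normal(G)
    )
    tumor_mu = base_mu.copy()
    if config.background_log2fc_sd > 0:
        lfc = config.background_log2fc_sd * rng.standard_normal(G)
        lfc[driver_idx] = 0.0  # drivers shift through their latent displacement
        tumor_mu = base_mu * 2.0 ** lfc

    counts_ref = _nb_counts(z_ref, base_mu[:, None], config.nb_dispersion)
    counts_tum = _nb_counts(z_tum, tumor_mu[:, None], config.nb_dispersion)

    ref_ids = [f"REF{i:03d}" for i in range(n_ref)]
    tum_ids = [f"TUM{i:03d}" for i in range(n_tum)]
    values = pd.DataFrame(
        np.concatenate([counts_ref, counts_tum], axis=1),
        index=pd.Index(gene_ids, name="gene_id"),
        columns=ref_ids + tum_ids,
    )
    sample_group = pd.Series(
        [REFERENCE] * n_ref + [TUMOR] * n_tum, index=values.columns
    )
    expr = ExpressionMatrix(values=values, gene_info=gene_info, sample_group=sample_group)

    # survival: log-hazard linear in standardized driver log2 expression
    log_expr = np.log2(counts_tum[driver_idx] + 1.0)
    sd = log_expr.std(axis=1, ddof=0)
    sd[sd == 0] = 1.0
    z_drv = (log_expr - log_expr.mean(axis=1, keepdims=True)) / sd[:, None]
    beta = np.asarray(config.hazard_coefficients, dtype=float)
    hazard = config.baseline_hazard * np.exp(beta @ z_drv)
    t_event = rng.exponential(1.0 / hazard)
    if config.censoring_rate > 0:
        t_cens = rng.exponential(1.0 / config.censoring_rate, size=n_tum)
    else:
        t_cens = np.full(n_tum, np.inf)
    observed = np.minimum(t_event, t_cens)
    os_days = np.maximum(1, np.round(observed)).astype(int)
    event = (t_event <= t_cens).astype(int)

    clinical = pd.DataFrame(
        {
            "os_days": os_days,
            "event": event,
            "age": rng.integers(30, 86, size=n_tum),
            "sex": rng.choice(["male", "female"], size=n_tum, p=[0.68, 0.32]),
            "weight": np.round(
                np.clip(rng.normal(75, 15, size=n_tum), 40, 160), 1
            ),
            "grade": rng.choice([1, 2, 3, 4], size=n_tum, p=[0.15, 0.40, 0.30, 0.15]),
            "stage": rng.choice([1, 2, 3, 4], size=n_tum, p=[0.45, 0.25, 0.20, 0.10]),
            "group": TUMOR,
        },
        index=pd.Index(tum_ids, name="sample_id"),
    )[CLINICAL_COLUMNS]

    driver_ids = [lnc_ids[d] for d in driver_idx]
    partner_map = {
        lnc_ids[d]: [mrna_ids[j] for j in np.flatnonzero(mrna_module == lnc_module[d])]
        for d in driver_idx
    }
    truth = SyntheticTruth(
        driver_lnc_ids=driver_ids,
        partner_map=partner_map,
        true_beta={lnc_ids[d]: float(b) for d, b in zip(driver_idx, beta)},
    )
    return expr, clinical, truth
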