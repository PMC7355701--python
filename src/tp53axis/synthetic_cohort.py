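"""Synthetic case-control cohort generator.

Individual-level genotypes for the motivating AML case-control study (406
healthy controls, 403 adult AML patients, four candidate loci on the p53
regulatory axis) are not publicly deposited, so every downstream stage of
this package is exercised on simulated cohorts that reproduce the cohort's
published statistical structure:

* per-locus variant-allele frequencies taken from the published control
  genotype distribution;
* the two *MDM2* loci drawn as haplotype pairs with strong linkage
  disequilibrium (|D'| ~ 0.89 in controls);
* optional Hardy–Weinberg departure via a per-locus inbreeding coefficient
  F (the *MDM4* locus departs from HWE in both study groups; F is the
  minimal one-parameter emulator of that departure);
* binary covariates (male sex, age >= 60) with control-group prevalences;
* disease status from a logistic model whose linear predictor combines
  genotype-coding indicators, covariates and product (interaction) terms.

Case-control ascertainment is emulated by rejection sampling from the
population model until both group quotas are filled — exact under the
logistic model and cheap at this scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .core_data_io import DEFAULT_LOCI, Cohort

# ---------------------------------------------------------------------------
# published genotype distribution (counts) of the motivating study cohort
# ---------------------------------------------------------------------------

#: (dosage-0, dosage-1, dosage-2) counts among the 406 controls.
CONTROL_GENOTYPE_COUNTS: dict[str, tuple[int, int, int]] = {
    "TP53_rs1042522": (217, 152, 37),
    "MDM2_rs2279744": (141, 197, 68),
    "MDM2_rs3730485": (179, 169, 58),
    "MDM4_rs4245739": (83, 114, 209),
}

#: (dosage-0, dosage-1, dosage-2) counts among the 403 AML cases.
CASE_GENOTYPE_COUNTS: dict[str, tuple[int, int, int]] = {
    "TP53_rs1042522": (225, 110, 68),
    "MDM2_rs2279744": (135, 213, 55),
    "MDM2_rs3730485": (168, 185, 50),
    "MDM4_rs4245739": (57, 144, 202),
}

#: Sex composition (male, female) of cases and controls.
SEX_COUNTS = {"cases": (215, 188), "controls": (181, 225)}
#: Subjects aged >= 60 (cases out of 403, controls out of 406).
AGE_GE60_COUNTS = {"cases": 196, "controls": 221}


def variant_allele_freq(counts: tuple[int, int, int]) -> float:
    n0, n1, n2 = counts
    return (2 * n2 + n1) / (2 * (n0 + n1 + n2))


def inbreeding_coefficient(counts: tuple[int, int, int]) -> float:
    """F = 1 - observed/expected heterozygosity; 0 under HWE."""
    n0, n1, n2 = counts
    n = n0 + n1 + n2
    p = variant_allele_freq(counts)
    exp_het = 2.0 * p * (1.0 - p)
    if exp_het == 0:
        return 0.0
    return 1.0 - (n1 / n) / exp_het


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------

_MDM2_A = "MDM2_rs2279744"   # haplotype locus 1 (T > G)
_MDM2_B = "MDM2_rs3730485"   # haplotype locus 2 (I > D)

#: Main-effect and interaction log-odds of the study's joint recessive
#: interaction model, used as the replica generative model; covariate
#: log-odds derived from the published sex / age-group composition.
STUDY_BETAS: dict[str, float] = {
    "recessive(MDM2_rs2279744)": -0.41,
    "recessive(TP53_rs1042522)": 0.51,
    "recessive(MDM4_rs4245739)": 0.10,
    "recessive(MDM2_rs3730485)": 0.26,
    "recessive(MDM2_rs2279744)*recessive(TP53_rs1042522)": 1.22,
    "recessive(MDM4_rs4245739)*recessive(MDM2_rs3730485)": -0.92,
    "male": 0.35,
    "age_ge60": -0.23,
}


def haplotype_freqs_from_dprime(p1: float, p2: float,
                                dprime: float) -> tuple[float, float, float, float]:
    """Two-locus haplotype frequencies (wt-wt, wt-var, var-wt, var-var)
    with variant-allele frequencies ``p1``, ``p2`` and a chosen signed D'
    (positive couples the two variant alleles)."""
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("allele frequencies must be in (0, 1)")
    if dprime >= 0:
        dmax = min((1 - p1) * p2, p1 * (1 - p2))
    else:
        dmax = min(p1 * p2, (1 - p1) * (1 - p2))
    d = dprime * dmax
    freqs = ((1 - p1) * (1 - p2) + d, (1 - p1) * p2 - d,
             p1 * (1 - p2) - d, p1 * p2 + d)
    if min(freqs) < -1e-12:
        raise ValueError("infeasible D' for the given allele frequencies")
    return tuple(max(f, 0.0) for f in freqs)  # type: ignore[return-value]


def _default_hap_freqs() -> tuple[float, float, float, float]:
    pG = variant_allele_freq(CONTROL_GENOTYPE_COUNTS[_MDM2_A])
    pD = variant_allele_freq(CONTROL_GENOTYPE_COUNTS[_MDM2_B])
    return haplotype_freqs_from_dprime(pG, pD, 0.89)


@dataclass(frozen=True)
class SimulationConfig:
    """Generative model for a case-control cohort.

    Defaults reproduce the motivating study's conditions: group sizes
    403/406, control-derived allele and haplotype frequencies with
    |D'| = 0.89 between the two *MDM2* loci, the observed *MDM4* HWE
    departure, control covariate prevalences, and the study's joint
    recessive interaction model as disease model.
    """

    seed: int = 0
    n_cases: int = 403
    n_controls: int = 406
    #: frequencies of the rs2279744 × rs3730485 haplotypes (T-I, T-D, G-I, G-D)
    hap_freqs_mdm2: tuple[float, float, float, float] = field(
        default_factory=_default_hap_freqs)
    maf_tp53: float = variant_allele_freq(CONTROL_GENOTYPE_COUNTS["TP53_rs1042522"])
    maf_mdm4: float = variant_allele_freq(CONTROL_GENOTYPE_COUNTS["MDM4_rs4245739"])
    #: per-locus inbreeding coefficient in [0, 1); keys are locus ids
    inbreeding_f: Mapping[str, float] = field(default_factory=lambda: {
        "MDM4_rs4245739": inbreeding_coefficient(
            CONTROL_GENOTYPE_COUNTS["MDM4_rs4245739"])})
    p_age_ge60: float = AGE_GE60_COUNTS["controls"] / 406
    p_male: float = SEX_COUNTS["controls"][0] / 406
    beta0: float = -1.0
    #: design-term -> log-odds; terms are covariate names ("male",
    #: "age_ge60") or "coding(locus_id)" indicators with coding in
    #: {dominant, recessive, overdominant, additive}; "*" joins product terms
    betas: Mapping[str, float] = field(default_factory=lambda: dict(STUDY_BETAS))
    #: optional locus_id -> (P(d=0), P(d=1), P(d=2)) replacing the
    #: haplotype/HWE draw at that locus (loses LD for overridden loci);
    #: used to match an observed marginal genotype distribution exactly
    genotype_probs_override: Mapping[str, tuple[float, float, float]] = field(
        default_factory=dict)
    max_draws: int = 2_000_000

    def __post_init__(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("group sizes must be positive")
        hf = self.hap_freqs_mdm2
        if len(hf) != 4 or min(hf) < 0 or abs(sum(hf) - 1.0) > 1e-9:
            raise ValueError("hap_freqs_mdm2 must be 4 nonnegative freqs summing to 1")
        for p in (self.maf_tp53, self.maf_mdm4, self.p_age_ge60, self.p_male):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lid, f in self.inbreeding_f.items():
            if not 0.0 <= f < 1.0:
                raise ValueError(f"inbreeding_f[{lid}] must lie in [0, 1)")
        for lid, probs in self.genotype_probs_override.items():
            if len(probs) != 3 or min(probs) < 0 or abs(sum(probs) - 1) > 1e-9:
                raise ValueError(f"override for {lid} must be 3 probs summing to 1")

    def to_dict(self) -> dict:
        return {"seed": self.seed, "n_cases": self.n_cases,
                "n_controls": self.n_controls,
                "hap_freqs_mdm2": list(self.hap_freqs_mdm2),
                "maf_tp53": self.maf_tp53, "maf_mdm4": self.maf_mdm4,
                "inbreeding_f": dict(self.inbreeding_f),
                "p_age_ge60": self.p_age_ge60, "p_male": self.p_male,
                "beta0": self.beta0, "betas": dict(self.betas),
                "genotype_probs_override": {k: list(v) for k, v in
                                            self.genotype_probs_override.items()},
                "max_draws": self.max_draws}

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "hap_freqs_mdm2" in d:
            d["hap_freqs_mdm2"] = tuple(d["hap_freqs_mdm2"])
        if "genotype_probs_override" in d:
            d["genotype_probs_override"] = {
                k: tuple(v) for k, v in d["genotype_probs_override"].items()}
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def preset(name: str, seed: int = 0) -> SimulationConfig:
    """Named study conditions.

    ``study_replica``
        The default config: observed frequencies + the joint recessive
        interaction disease model.
    ``null``
        Same population structure, no genetic or covariate effects.
    ``observed_controls``
        No effects; every locus drawn from the published control genotype
        distribution exactly (marginal overrides, no LD) — used for
        genotype-frequency checks.
    ``interaction_gg_propro``
        Only the TP53 recessive main effect and the rs2279744 × rs1042522
        recessive interaction planted.
    """
    base = SimulationConfig(seed=seed)
    if name == "study_replica":
        return base
    if name == "null":
        return replace(base, betas={})
    if name == "observed_controls":
        override = {lid: tuple(np.asarray(c) / sum(c))
                    for lid, c in CONTROL_GENOTYPE_COUNTS.items()}
        return replace(base, betas={}, genotype_probs_override=override)
    if name == "interaction_gg_propro":
        return replace(base, betas={
            "recessive(TP53_rs1042522)": 0.51,
            "recessive(MDM2_rs2279744)*recessive(TP53_rs1042522)": 1.22})
    raise KeyError(f"unknown preset {name!r}")


# ---------------------------------------------------------------------------
# design-term evaluation
# ---------------------------------------------------------------------------

_CODING_FUNCS = {
    "dominant": lambda d: (d >= 1).astype(float),
    "recessive": lambda d: (d == 2).astype(float),
    "overdominant": lambda d: (d == 1).astype(float),
    "additive": lambda d: d.astype(float),
}


def _eval_factor(factor: str, dosages: Mapping[str, np.ndarray],
                 covars: Mapping[str, np.ndarray]) -> np.ndarray:
    factor = factor.strip()
    if factor in covars:
        return covars[factor].astype(float)
    if "(" in factor and factor.endswith(")"):
        coding, locus = factor[:-1].split("(", 1)
        if coding not in _CODING_FUNCS:
            raise ValueError(f"unknown coding {coding!r} in term {factor!r}")
        if locus not in dosages:
            raise ValueError(f"unknown locus {locus!r} in term {factor!r}")
        return _CODING_FUNCS[coding](dosages[locus])
    raise ValueError(f"cannot parse design term {factor!r}")


def evaluate_term(term: str, dosages: Mapping[str, np.ndarray],
                  covars: Mapping[str, np.ndarray]) -> np.ndarray:
    """Evaluate one design term ("*"-joined product of factors)."""
    cols = [_eval_factor(f, dosages, covars) for f in term.split("*")]
    return np.prod(np.stack(cols, axis=0), axis=0)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def genotype_probs(p: float, f: float = 0.0) -> tuple[float, float, float]:
    """Genotype probabilities for variant frequency ``p`` and inbreeding
    ``f``: P(het) = (1-f)·2p(1-p), P(hom-var) = f·p + (1-f)·p²."""
    q = 1.0 - p
    return (f * q + (1 - f) * q * q, (1 - f) * 2 * p * q, f * p + (1 - f) * p * p)


def _draw_block(cfg: SimulationConfig, rng: np.random.Generator,
                size: int) -> pd.DataFrame:
    hap = rng.choice(4, size=(size, 2), p=np.asarray(cfg.hap_freqs_mdm2))
    # haplotypes (T-I, T-D, G-I, G-D): G on indices {2,3}, D on {1,3}
    d_2279744 = (hap >= 2).sum(axis=1)
    d_3730485 = ((hap == 1) | (hap == 3)).sum(axis=1)
    dosages = {_MDM2_A: d_2279744, _MDM2_B: d_3730485}
    for lid, p in (("TP53_rs1042522", cfg.maf_tp53),
                   ("MDM4_rs4245739", cfg.maf_mdm4)):
        probs = genotype_probs(p, cfg.inbreeding_f.get(lid, 0.0))
        dosages[lid] = rng.choice(3, size=size, p=np.asarray(probs))
    for lid, probs in cfg.genotype_probs_override.items():
        dosages[lid] = rng.choice(3, size=size, p=np.asarray(probs))
    covars = {"male": (rng.random(size) < cfg.p_male).astype(int),
              "age_ge60": (rng.random(size) < cfg.p_age_ge60).astype(int)}
    eta = np.full(size, cfg.beta0, dtype=float)
    for term, beta in cfg.betas.items():
        eta += beta * evaluate_term(term, dosages, covars)
    prob = 1.0 / (1.0 + np.exp(-eta))
    status = (rng.random(size) < prob).astype(int)
    return pd.DataFrame({"status": status, "sex": covars["male"],
                         "age_ge60": covars["age_ge60"],
                         **{lid: dosages[lid] for lid, _ in
                            ((l.locus_id, None) for l in DEFAULT_LOCI)}})


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Draw a cohort with exactly the configured group sizes.

    Population subjects are drawn in blocks and assigned to the case or
    control pool by their simulated status until both quotas are filled;
    deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    want = {1: config.n_cases, 0: config.n_controls}
    pools = {0: [], 1: []}
    drawn = 0
    block = max(2048, (config.n_cases + config.n_controls) // 2)
    while any(sum(len(p) for p in pools[s]) < want[s] for s in (0, 1)):
        if drawn >= config.max_draws:
            raise RuntimeError(
                f"case/control quota unreachable within {config.max_draws} draws "
                f"(got {sum(len(p) for p in pools[1])} cases, "
                f"{sum(len(p) for p in pools[0])} controls)")
        df = _draw_block(config, rng, block)
        drawn += block
        for s in (0, 1):
            need = want[s] - sum(len(p) for p in pools[s])
            if need > 0:
                pools[s].append(df[df["status"] == s].head(need))
    out = pd.concat(pools[0] + pools[1], ignore_index=True)
    out.insert(0, "subject_id",
               [f"S{i + 1:04d}" for i in range(len(out))])
    for l in DEFAULT_LOCI:
        out[l.locus_id] = out[l.locus_id].astype("Int64")
    return Cohort(DEFAULT_LOCI, out)


def cohort_from_marginal_counts(
        control_counts: Mapping[str, tuple[int, int, int]] = CONTROL_GENOTYPE_COUNTS,
        case_counts: Mapping[str, tuple[int, int, int]] = CASE_GENOTYPE_COUNTS,
        sex_counts: Mapping[str, tuple[int, int]] | None = None,
        age_ge60_counts: Mapping[str, int] | None = None) -> Cohort:
    """Deterministic cohort whose per-locus marginal genotype counts (and
    optionally sex / age-group composition) equal the given tables.

    The joint genotype structure is arbitrary (dosages are laid out in
    sorted blocks per group), so the result is only meaningful for
    single-locus analyses and marginal summaries — exactly what is needed
    to reproduce published per-locus statistics from printed count tables.
    """
    if len({sum(c) for c in control_counts.values()}) != 1 or \
       len({sum(c) for c in case_counts.values()}) != 1:
        raise ValueError("per-locus counts must agree on group size")
    n_ctrl = sum(next(iter(control_counts.values())))
    n_case = sum(next(iter(case_counts.values())))
    loci = [l for l in DEFAULT_LOCI if l.locus_id in control_counts]

    def block(counts: Mapping[str, tuple[int, int, int]]) -> pd.DataFrame:
        return pd.DataFrame({lid: np.repeat([0, 1, 2], list(c))
                             for lid, c in counts.items()})

    ctrl = block(control_counts)
    case = block(case_counts)
    ctrl.insert(0, "status", 0)
    case.insert(0, "status", 1)
    df = pd.concat([ctrl, case], ignore_index=True)
    sex = np.zeros(len(df), dtype=int)
    age = np.zeros(len(df), dtype=int)
    if sex_counts:
        m_ctrl, _ = sex_counts["controls"]
        m_case, _ = sex_counts["cases"]
        sex[:m_ctrl] = 1
        sex[n_ctrl:n_ctrl + m_case] = 1
    if age_ge60_counts:
        age[:age_ge60_counts["controls"]] = 1
        age[n_ctrl:n_ctrl + age_ge60_counts["cases"]] = 1
    df["sex"], df["age_ge60"] = sex, age
    df.insert(0, "subject_id", [f"S{i + 1:04d}" for i in range(len(df))])
    for l in loci:
        df[l.locus_id] = df[l.locus_id].astype("Int64")
    return Cohort(loci, df)


# ---------------------------------------------------------------------------
# closed-form LD of the configured haplotype distribution
# ---------------------------------------------------------------------------

def expected_ld(config: SimulationConfig) -> tuple[float, float, float]:
    """(D, D', r²) implied by ``config.hap_freqs_mdm2``.

    D is computed between the two wild-type alleles (T and I); D' carries
    its sign, |D'| is the conventional report.  Raises for a monomorphic
    locus, where D' is undefined.
    """
    f_ti, f_td, f_gi, f_gd = config.hap_freqs_mdm2
    p_t = f_ti + f_td
    p_i = f_ti + f_gi
    if p_t in (0.0, 1.0) or p_i in (0.0, 1.0):
        raise ValueError("D' undefined for a monomorphic locus")
    d = f_ti - p_t * p_i
    if d >= 0:
        dmax = min(p_t * (1 - p_i), (1 - p_t) * p_i)
    else:
        dmax = min(p_t * p_i, (1 - p_t) * (1 - p_i))
    dprime = d / dmax if dmax > 0 else 0.0
    r2 = d * d / (p_t * (1 - p_t) * p_i * (1 - p_i))
    return d, dprime, r2
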