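"""Cohort data model, genotype coding and tabular I/O.

The analysis operates on a case-control cohort genotyped at a small set of
named biallelic loci (here the p53 regulatory axis: one *TP53*, two *MDM2*
and one *MDM4* variant).  Each locus has a fixed "variant" allele chosen by
configuration — not inferred from sample frequency, since allele-orientation
conventions for these variants have flipped between annotation releases —
and genotypes are coded as the dosage of that variant allele (0, 1 or 2).

Subjects carry a binary disease status (1 = case, 0 = control) and two
binary covariates: sex (male = 1, female = 0) and age group (1 = age at
diagnosis/enrolment >= 60 years).
"""

from __future__ import annotations

import csv
import io
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

logger = logging.getLogger("tp53axis")

#: Mandatory non-genotype columns of a cohort table, in canonical order.
MANDATORY_COLUMNS = ("subject_id", "status", "sex", "age_ge60")

#: Accepted spellings for the binary sex column (male = 1).
_SEX_CODES = {"m": 1, "male": 1, "1": 1, "f": 0, "female": 0, "0": 0}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LocusDef:
    """A biallelic locus with a fixed variant-allele orientation.

    Parameters
    ----------
    locus_id : str
        Unique identifier, conventionally ``<GENE>_<rsid>``.
    gene : str
        Gene symbol.
    allele_wt, allele_var : str
        Allele labels; ``allele_var`` is the allele whose dosage is counted.
        May be amino acids ("Arg"/"Pro"), nucleotides ("T"/"G", "C"/"A") or
        indel codes ("I"/"D").
    """

    locus_id: str
    gene: str
    allele_wt: str
    allele_var: str

    def __post_init__(self) -> None:
        if self.allele_wt == self.allele_var:
            raise ValueError(f"{self.locus_id}: alleles must differ")

    @property
    def genotype_labels(self) -> tuple[str, str, str]:
        """Canonical genotype strings for dosages 0, 1, 2."""
        w, v = self.allele_wt, self.allele_var
        return (f"{w}/{w}", f"{w}/{v}", f"{v}/{v}")

    def encode(self, genotype: str) -> int | None:
        """Map a genotype string to variant-allele dosage (heterozygote
        order-insensitive); ``None`` for unparseable strings."""
        if not isinstance(genotype, str):
            return None
        parts = genotype.strip().split("/")
        if len(parts) != 2:
            return None
        alleles = {self.allele_wt: 0, self.allele_var: 1}
        try:
            return alleles[parts[0].strip()] + alleles[parts[1].strip()]
        except KeyError:
            return None

    def decode(self, dosage: int) -> str:
        return self.genotype_labels[int(dosage)]


#: Default locus panel of the motivating AML case-control study.  Variant
#: orientation matches the published genotype tables: Pro, G, D(el) and A
#: are the counted alleles (for the MDM4 variant the current reference
#: allele is C, so A — the ancestral allele — is "variant" here).
DEFAULT_LOCI: tuple[LocusDef, ...] = (
    LocusDef("TP53_rs1042522", "TP53", "Arg", "Pro"),
    LocusDef("MDM2_rs2279744", "MDM2", "T", "G"),
    LocusDef("MDM2_rs3730485", "MDM2", "I", "D"),
    LocusDef("MDM4_rs4245739", "MDM4", "C", "A"),
)


@dataclass(frozen=True)
class Subject:
    subject_id: str
    status: int
    sex: int
    age_ge60: int
    genotypes: Mapping[str, int | None] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("status", "sex", "age_ge60"):
            if getattr(self, name) not in (0, 1):
                raise ValueError(f"{self.subject_id}: {name} must be 0/1")
        for locus, d in self.genotypes.items():
            if d is not None and d not in (0, 1, 2):
                raise ValueError(f"{self.subject_id}: bad dosage {d!r} at {locus}")


class Cohort:
    """A validated case-control cohort.

    Internally a :class:`pandas.DataFrame` with the mandatory columns plus
    one nullable-integer dosage column per locus; ``loci`` fixes the locus
    order used throughout the package.
    """

    def __init__(self, loci: Sequence[LocusDef], data: pd.DataFrame):
        self.loci = tuple(loci)
        known = {l.locus_id for l in self.loci}
        for col in MANDATORY_COLUMNS:
            if col not in data.columns:
                raise ValueError(f"cohort table lacks mandatory column {col!r}")
        extra = [c for c in data.columns if c not in MANDATORY_COLUMNS]
        unknown = [c for c in extra if c not in known]
        if unknown:
            raise ValueError(f"genotype column(s) absent from locus config: {unknown}")
        df = data.copy()
        for name in ("status", "sex", "age_ge60"):
            vals = set(pd.unique(df[name].dropna()))
            if not vals <= {0, 1}:
                raise ValueError(f"column {name!r} must be binary 0/1, got {vals}")
            df[name] = df[name].astype(np.int64)
        for l in self.loci:
            if l.locus_id not in df.columns:
                df[l.locus_id] = pd.array([pd.NA] * len(df), dtype="Int64")
            else:
                df[l.locus_id] = df[l.locus_id].astype("Int64")
                bad = df[l.locus_id].dropna()
                if len(bad) and not bad.isin([0, 1, 2]).all():
                    raise ValueError(f"{l.locus_id}: dosages outside 0/1/2")
        self.data = df[list(MANDATORY_COLUMNS) + [l.locus_id for l in self.loci]]
        self.data.reset_index(drop=True, inplace=True)

    # -- construction -------------------------------------------------------

    @classmethod
    def from_subjects(cls, loci: Sequence[LocusDef],
                      subjects: Iterable[Subject]) -> "Cohort":
        rows = []
        for s in subjects:
            row = {"subject_id": s.subject_id, "status": s.status,
                   "sex": s.sex, "age_ge60": s.age_ge60}
            for l in loci:
                d = s.genotypes.get(l.locus_id)
                row[l.locus_id] = pd.NA if d is None else d
            rows.append(row)
        columns = list(MANDATORY_COLUMNS) + [l.locus_id for l in loci]
        df = pd.DataFrame(rows, columns=columns)
        if df.empty:
            df = df.astype({c: np.int64 for c in ("status", "sex", "age_ge60")})
        for l in loci:
            df[l.locus_id] = df[l.locus_id].astype("Int64")
        return cls(loci, df)

    # -- basic accessors ----------------------------------------------------

    def __len__(self) -> int:
        return len(self.data)

    @property
    def n_cases(self) -> int:
        return int((self.data["status"] == 1).sum())

    @property
    def n_controls(self) -> int:
        return int((self.data["status"] == 0).sum())

    @property
    def locus_ids(self) -> tuple[str, ...]:
        return tuple(l.locus_id for l in self.loci)

    def locus(self, locus_id: str) -> LocusDef:
        for l in self.loci:
            if l.locus_id == locus_id:
                return l
        raise KeyError(f"unknown locus {locus_id!r}")

    def subjects(self) -> list[Subject]:
        out = []
        for _, r in self.data.iterrows():
            geno = {l.locus_id: (None if pd.isna(r[l.locus_id]) else int(r[l.locus_id]))
                    for l in self.loci}
            out.append(Subject(str(r["subject_id"]), int(r["status"]),
                               int(r["sex"]), int(r["age_ge60"]), geno))
        return out

    def complete_cases(self, locus_ids: Sequence[str]) -> pd.DataFrame:
        """Rows with non-missing dosage at every requested locus."""
        for lid in locus_ids:
            self.locus(lid)
        mask = np.ones(len(self.data), dtype=bool)
        for lid in locus_ids:
            mask &= self.data[lid].notna().to_numpy()
        n_dropped = int((~mask).sum())
        if n_dropped:
            logger.info("complete-case filter on %s dropped %d subject(s)",
                        ",".join(locus_ids), n_dropped)
        return self.data.loc[mask]


@dataclass
class GenotypeCounts:
    """Status × dosage counts at one locus (missing excluded)."""

    locus_id: str
    genotype_labels: tuple[str, str, str]
    counts: np.ndarray          # shape (2, 3); row 0 = controls, row 1 = cases
    n_missing: tuple[int, int]  # (controls, cases)

    @property
    def percentages(self) -> np.ndarray:
        totals = self.counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(totals > 0, 100.0 * self.counts / totals, 0.0)

    def to_frame(self) -> pd.DataFrame:
        pct = self.percentages
        return pd.DataFrame(
            {"genotype": self.genotype_labels,
             "controls_n": self.counts[0], "controls_pct": pct[0].round(1),
             "cases_n": self.counts[1], "cases_pct": pct[1].round(1)})


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_locus_config(path: str | Path) -> list[LocusDef]:
    """Read a locus-definition config (YAML or JSON list of mappings)."""
    text = Path(path).read_text()
    payload = yaml.safe_load(text)
    if isinstance(payload, dict) and "loci" in payload:
        payload = payload["loci"]
    loci = [LocusDef(e["locus_id"], e.get("gene", ""), e["allele_wt"], e["allele_var"])
            for e in payload]
    ids = [l.locus_id for l in loci]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate locus_id in config")
    return loci


def write_locus_config(loci: Sequence[LocusDef], path: str | Path) -> None:
    payload = [{"locus_id": l.locus_id, "gene": l.gene,
                "allele_wt": l.allele_wt, "allele_var": l.allele_var}
               for l in loci]
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _sniff_delimiter(header_line: str) -> str:
    return "\t" if "\t" in header_line else ","


def read_cohort(table_path: str | Path,
                locus_config_path: str | Path | None = None,
                loci: Sequence[LocusDef] | None = None) -> Cohort:
    """Read a subject-level cohort table (TSV/CSV, auto-detected).

    Genotype columns hold strings like ``"Arg/Pro"``; heterozygotes are
    order-insensitive.  Unparseable genotypes become missing, with the
    total warned once per locus.
    """
    if loci is None:
        if locus_config_path is None:
            raise ValueError("either locus_config_path or loci is required")
        loci = read_locus_config(locus_config_path)
    text = Path(table_path).read_text()
    delim = _sniff_delimiter(text.splitlines()[0] if text else "")
    df = pd.read_csv(io.StringIO(text), sep=delim, dtype=str,
                     skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cohort table lacks mandatory column {col!r}")
    known = {l.locus_id for l in loci}
    geno_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    unknown = [c for c in geno_cols if c not in known]
    if unknown:
        raise ValueError(f"genotype column(s) absent from locus config: {unknown}")

    out = pd.DataFrame({"subject_id": df["subject_id"].astype(str)})
    for name in ("status", "age_ge60"):
        out[name] = pd.to_numeric(df[name])
    out["sex"] = [_SEX_CODES.get(str(v).strip().lower(), v) for v in df["sex"]]
    out["sex"] = pd.to_numeric(out["sex"])
    for l in loci:
        if l.locus_id not in df.columns:
            continue
        coded = [l.encode(g) for g in df[l.locus_id]]
        n_bad = sum(1 for raw, c in zip(df[l.locus_id], coded)
                    if c is None and isinstance(raw, str) and raw.strip() not in ("", "NA", "."))
        if n_bad:
            logger.warning("%s: %d unparseable genotype(s) set to missing",
                           l.locus_id, n_bad)
        out[l.locus_id] = pd.array([pd.NA if c is None else c for c in coded],
                                   dtype="Int64")
    return Cohort(loci, out)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    """Write a cohort as TSV with canonical genotype strings.

    write → read → write round-trips byte-identically.
    """
    df = cohort.data.copy()
    for l in cohort.loci:
        df[l.locus_id] = [("NA" if pd.isna(d) else l.decode(int(d)))
                          for d in df[l.locus_id]]
    df["sex"] = np.where(df["sex"] == 1, "M", "F")
    with open(path, "w", newline="") as fh:
        df.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def write_manifest(path: str | Path, *, seed: int | None = None,
                   config: Mapping | None = None, **extra) -> None:
    """Write a JSON run manifest (config, seed, package versions)."""
    import statsmodels

    manifest = {
        "seed": seed,
        "config": dict(config) if config else None,
        "versions": {"tp53axis": _version(), "numpy": np.__version__,
                     "scipy": __import__("scipy").__version__,
                     "pandas": pd.__version__,
                     "statsmodels": statsmodels.__version__},
        **extra,
    }
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _version() -> str:
    from importlib.metadata import version
    try:
        return version("tp53axis")
    except Exception:
        return "unknown"


# ---------------------------------------------------------------------------
# tabulation & demographics
# ---------------------------------------------------------------------------

def tabulate(cohort: Cohort, locus_id: str) -> GenotypeCounts:
    """Status × dosage genotype counts at one locus, missing excluded."""
    locus = cohort.locus(locus_id)
    col = cohort.data[locus_id]
    counts = np.zeros((2, 3), dtype=np.int64)
    missing = [0, 0]
    for status in (0, 1):
        sub = col[cohort.data["status"] == status]
        missing[status] = int(sub.isna().sum())
        vc = sub.dropna().astype(int).value_counts()
        for d in (0, 1, 2):
            counts[status, d] = int(vc.get(d, 0))
    return GenotypeCounts(locus_id, locus.genotype_labels, counts,
                          (missing[0], missing[1]))


def summarize_demographics(cohort: Cohort) -> dict:
    """Group sizes, sex and age-group composition, the case-group
    male-to-female ratio, and the sex × status Pearson chi-square p-value
    (2×2, no continuity correction)."""
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    df = cohort.data
    out: dict = {}
    for status, name in ((0, "controls"), (1, "cases")):
        g = df[df["status"] == status]
        out[name] = {"n": len(g),
                     "male": int((g["sex"] == 1).sum()),
                     "female": int((g["sex"] == 0).sum()),
                     "age_ge60": int((g["age_ge60"] == 1).sum())}
    c = out["cases"]
    out["male_female_ratio_cases"] = (c["male"] / c["female"]
                                      if c["female"] > 0 else None)
    table = np.array([[out["cases"]["male"], out["cases"]["female"]],
                      [out["controls"]["male"], out["controls"]["female"]]])
    if table.sum() and (table.sum(0) > 0).all() and (table.sum(1) > 0).all():
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        out["sex_status_chi2"], out["sex_status_p"] = float(chi2), float(p)
    else:
        out["sex_status_chi2"] = out["sex_status_p"] = None
    return out
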