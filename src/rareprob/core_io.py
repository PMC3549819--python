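"""Domain types and file input/output for case-control rare-variant data.

Genotypes are dominant-coded carrier indicators: entry ``G[s, i]`` is 1 when
individual ``i`` carries at least one mutant allele at variant ``s`` and 0 when
both haplotypes are wild type.  Tables are TSV with variants as rows (first
column the variant id, header row of sample ids); VCF import collapses any
genotype call with >= 1 non-reference allele to a carrier.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("rareprob")

#: default genome-wide significance threshold (Bonferroni over 20,000 genes)
DEFAULT_SIGNIFICANCE_THRESHOLD = 2.5e-6

#: numerical floors used throughout the package
PROB_FLOOR = 1e-300
RATE_CLAMP = 1e-6


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


class ParseError(ValueError):
    """Raised when a file cannot be parsed in its declared dialect."""


@dataclass
class GenotypeMatrix:
    """Binary carrier matrix, M variants x N individuals."""

    values: np.ndarray
    variant_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValidationError("genotype matrix must be 2-dimensional")
        m, n = self.values.shape
        if m < 1 or n < 2:
            raise ValidationError(f"need M >= 1 variants and N >= 2 samples, got {m} x {n}")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("genotype entries must be 0 or 1")
        self.values = self.values.astype(np.int8)
        self.variant_ids = [str(v) for v in self.variant_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if len(self.variant_ids) != m:
            raise ValidationError("variant_ids length does not match row count")
        if len(self.sample_ids) != n:
            raise ValidationError("sample_ids length does not match column count")
        if len(set(self.variant_ids)) != m:
            raise ValidationError("variant ids must be unique")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample ids must be unique")

    @property
    def n_variants(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass
class Phenotypes:
    """Dichotomous phenotype vector (1 = case, 0 = control)."""

    status: np.ndarray

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status)
        if not np.isin(self.status, (0, 1)).all():
            raise ValidationError("phenotype status must be 0 or 1")
        self.status = self.status.astype(np.int8)
        if self.n_case < 1 or self.n_ctrl < 1:
            raise ValidationError("need at least one case and one control")

    @property
    def n_case(self) -> int:
        return int(self.status.sum())

    @property
    def n_ctrl(self) -> int:
        return int(self.status.size - self.status.sum())

    @property
    def case_mask(self) -> np.ndarray:
        return self.status == 1


@dataclass
class PriorScores:
    """Optional per-variant functional scores in [0, 1] (e.g. from external
    deleteriousness predictors) used only to seed the initial hidden states."""

    causal_hint: Optional[np.ndarray] = None
    region_hint: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        for name in ("causal_hint", "region_hint"):
            v = getattr(self, name)
            if v is None:
                continue
            v = np.asarray(v, dtype=float)
            if v.ndim != 1 or ((v < 0) | (v > 1)).any():
                raise ValidationError(f"{name} must be a 1-d vector with values in [0, 1]")
            setattr(self, name, v)


@dataclass
class RunConfig:
    """Knobs of a model fit.

    seed
        drives any optional stochastic choices (e.g. random sweep order);
        the default fit is fully deterministic.
    max_iter
        cap on pseudo-likelihood estimation cycles.
    convergence_tol
        Euclidean-distance threshold on successive causal-state vectors;
        the default 1.0 stops as soon as a sweep flips no state.
    significance_threshold
        declared significance level for the final collapsing test.
    z_init, region_window
        initial-state construction: flag |z| >= z_init as causal, smooth
        over a centered window of region_window sites for the region seed.
    """

    seed: int = 0
    max_iter: int = 20
    convergence_tol: float = 1.0
    significance_threshold: float = DEFAULT_SIGNIFICANCE_THRESHOLD
    z_init: float = 1.0
    region_window: int = 10
    neighborhood_mode: str = "dense"
    min_abs_omega: float = 0.0
    random_sweep_order: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.significance_threshold < 1.0):
            raise ValidationError("significance_threshold must lie in (0, 1)")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if self.convergence_tol < 0:
            raise ValidationError("convergence_tol must be non-negative")
        if self.neighborhood_mode not in ("dense", "threshold"):
            raise ValidationError("neighborhood_mode must be 'dense' or 'threshold'")


def read_genotypes(path: str | Path, dialect: str = "table") -> GenotypeMatrix:
    """Read a genotype matrix from a TSV table or a VCF.

    Table dialect: rows = variants, first column variant id, header row of
    sample ids, entries in {0, 1} (``NA`` treated as 0 with a logged count).
    VCF dialect: any call with >= 1 non-reference allele becomes a carrier;
    missing calls ("./.") are treated as non-carriers with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "table":
        return _read_genotype_table(path)
    if dialect == "vcf":
        return _read_genotype_vcf(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def _read_genotype_table(path: Path) -> GenotypeMatrix:
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ParseError(f"cannot parse genotype table {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: genotype table needs >= 2 sample columns")
    n_missing = int(df.isin(["NA"]).to_numpy().sum())
    if n_missing:
        logger.warning("%s: %d missing genotype entries treated as non-carriers", path, n_missing)
    raw = df.replace("NA", "0")
    bad = ~raw.isin(["0", "1"])
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValidationError(
            f"{path}: non-binary genotype value {raw.iat[r, c]!r} at variant "
            f"{df.index[r]!r}, sample {df.columns[c]!r} (line {r + 2})"
        )
    return GenotypeMatrix(
        values=raw.to_numpy(dtype=np.int8),
        variant_ids=list(df.index.astype(str)),
        sample_ids=list(df.columns.astype(str)),
    )


def _read_genotype_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(path))
    except Exception as exc:
        raise ParseError(f"cannot open VCF {path}: {exc}") from exc
    sample_ids = list(vcf.samples)
    rows: list[np.ndarray] = []
    variant_ids: list[str] = []
    n_missing = 0
    for rec in vcf:
        calls = np.zeros(len(sample_ids), dtype=np.int8)
        for i, gt in enumerate(rec.genotypes):
            alleles = [a for a in gt[:-1] if a is not None]
            known = [a for a in alleles if a >= 0]
            if not known:
                n_missing += 1  # ./. -> non-carrier by policy
                continue
            # any non-reference allele (incl. multi-allelic) counts as mutant
            calls[i] = 1 if any(a > 0 for a in known) else 0
        rows.append(calls)
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}"
        variant_ids.append(vid)
    if n_missing:
        logger.warning("%s: %d missing VCF calls treated as non-carriers", path, n_missing)
    if not rows:
        raise ParseError(f"{path}: VCF contains no variant records")
    return GenotypeMatrix(np.vstack(rows), variant_ids, sample_ids)


def read_phenotypes(path: str | Path, sample_ids: Optional[Sequence[str]] = None) -> Phenotypes:
    """Read a two-column TSV (sample_id, status) and align to ``sample_ids``.

    When ``sample_ids`` is given (normally the genotype matrix sample order),
    statuses are joined onto that order; any unmatched sample is an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except Exception as exc:
        raise ParseError(f"cannot parse phenotype table {path}: {exc}") from exc
    if df.shape[1] != 2:
        raise ParseError(f"{path}: phenotype table must have exactly two columns")
    df.columns = ["sample_id", "status"]
    if not df["status"].isin(["0", "1"]).all():
        bad = df.loc[~df["status"].isin(["0", "1"]), "status"].iloc[0]
        raise ValidationError(f"{path}: phenotype status {bad!r} outside {{0, 1}}")
    table = dict(zip(df["sample_id"], df["status"].astype(int)))
    if len(table) != len(df):
        raise ValidationError(f"{path}: duplicate sample ids in phenotype table")
    if sample_ids is None:
        status = df["status"].astype(int).to_numpy()
    else:
        missing = [s for s in sample_ids if s not in table]
        if missing:
            raise ValidationError(f"{path}: no phenotype for sample(s) {missing[:5]}")
        status = np.array([table[s] for s in sample_ids], dtype=np.int8)
    return Phenotypes(status)


def write_genotypes(G: GenotypeMatrix, path: str | Path) -> None:
    """Write a genotype matrix in the TSV table dialect."""
    df = pd.DataFrame(G.values, index=G.variant_ids, columns=G.sample_ids)
    df.index.name = "variant_id"
    df.to_csv(path, sep="\t")


def write_phenotypes(P: Phenotypes, sample_ids: Sequence[str], path: str | Path) -> None:
    pd.DataFrame({"sample_id": list(sample_ids), "status": P.status}).to_csv(
        path, sep="\t", index=False
    )


def write_result(result, path: str | Path) -> dict[str, Path]:
    """Write a completed fit as a per-variant TSV plus JSON and text summaries.

    ``path`` is a stem: ``<path>.variants.tsv``, ``<path>.summary.json`` and
    ``<path>.summary.txt`` are produced.  Returns the paths written.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    variants_path = path.with_name(path.name + ".variants.tsv")
    json_path = path.with_name(path.name + ".summary.json")
    txt_path = path.with_name(path.name + ".summary.txt")

    table = pd.DataFrame(
        {
            "variant_id": result.variant_ids,
            "X_hat": result.X_hat.astype(int),
            "R_hat": result.R_hat.astype(int),
            "theta_hat": result.theta_hat,
            "rho_hat": result.rho_hat,
            "z": result.z,
        }
    )
    table.to_csv(variants_path, sep="\t", index=False)

    summary = {
        "n_variants": int(result.X_hat.size),
        "selected_risk": sorted(result.selected_risk),
        "selected_protective": sorted(result.selected_protective),
        "n_selected": int(result.X_hat.sum()),
        "statistic": float(result.statistic),
        "p_value": float(result.p_value),
        "significant": bool(result.significant),
        "n_iterations": int(result.n_iterations),
        "converged": bool(result.converged),
    }
    json_path.write_text(json.dumps(summary, indent=2) + "\n")

    lines = [
        "rare-variant HMRF selection + collapsing test",
        f"variants: {summary['n_variants']}",
        f"selected risk set ({len(summary['selected_risk'])}): "
        + (", ".join(summary["selected_risk"]) or "-"),
        f"selected protective set ({len(summary['selected_protective'])}): "
        + (", ".join(summary["selected_protective"]) or "-"),
        f"collapsing statistic: {summary['statistic']:.4f}",
        f"p-value: {summary['p_value']:.4g}",
        f"significant: {summary['significant']}",
        f"iterations: {summary['n_iterations']} (converged: {summary['converged']})",
    ]
    txt_path.write_text("\n".join(lines) + "\n")
    return {"variants": variants_path, "summary_json": json_path, "summary_txt": txt_path}
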