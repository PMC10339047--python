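"""GWAS summary statistics: I/O, instrument selection, proxies, harmonization.

A :class:`SumStatTable` holds one trait's per-variant association records
(effect sizes on the standardized scale for continuous traits, log-odds for
binary traits).  Instruments for Mendelian randomization are selected by
p-value thresholding plus greedy LD clumping, optionally excluding named
genomic regions (a preset ships for the widely pleiotropic GCKR locus).
Exposure and outcome effects are then aligned onto a common effect allele per
variant, resolving strand flips and palindromic A/T–G/C ambiguity by
allele-frequency concordance.

Coordinates are 1-based and region spans are inclusive.  All tables are plain
tab-separated text with a declared header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    EmptyHarmonizationError,
    EmptyInputError,
    EmptyInstrumentError,
    FormatError,
    InputError,
    VariantLookupError,
)

logger = logging.getLogger(__name__)

SUMSTAT_COLUMNS = [
    "variant_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pval", "n",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: GCKR region (chrom 2, 1-based inclusive) known for broad metabolic
#: pleiotropy with a primary hepatic effect; used as a sensitivity exclusion.
GCKR_REGION = ("2", 27219709, 28246554)


def gckr_exclusion_region(flank: int = 500_000) -> tuple[str, int, int]:
    """GCKR span widened by ``flank`` bp on each side (default 500 kb)."""
    chrom, start, end = GCKR_REGION
    return (chrom, max(1, start - flank), end + flank)


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class SumStatTable:
    """One GWAS trait's summary statistics, keyed by unique variant_id."""

    trait_name: str
    trait_type: str  # "continuous" | "binary"
    df: pd.DataFrame  # columns SUMSTAT_COLUMNS, indexed by variant_id

    def __post_init__(self) -> None:
        if self.trait_type not in ("continuous", "binary"):
            raise InputError(f"unknown trait_type {self.trait_type!r}")
        if not self.df.index.is_unique:
            raise InputError("variant_id must be unique within a table")

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self.df.index

    def record(self, variant_id: str) -> pd.Series:
        try:
            return self.df.loc[variant_id]
        except KeyError as exc:
            raise VariantLookupError(
                f"{variant_id} not in table {self.trait_name}") from exc


@dataclass
class LDMatrix:
    """Pairwise LD correlations (r, signed) for an ordered set of variants."""

    variant_ids: list[str]
    r: np.ndarray

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        k = len(self.variant_ids)
        if self.r.shape != (k, k):
            raise InputError("LD matrix shape does not match variant list")
        if not np.allclose(self.r, self.r.T, atol=1e-8):
            raise InputError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r), 1.0, atol=1e-6):
            raise InputError("LD matrix diagonal must be 1")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def r_between(self, a: str, b: str) -> float:
        try:
            return float(self.r[self._index[a], self._index[b]])
        except KeyError as exc:
            raise VariantLookupError(f"variant absent from LD matrix: {exc}")

    def r2_between(self, a: str, b: str) -> float:
        return self.r_between(a, b) ** 2


@dataclass
class InstrumentSet:
    """Selected (clumped) instruments for one exposure.

    ``provenance`` keeps one tag per candidate variant:
    ``direct``, ``proxy:<original_id>`` or ``removed:<reason>``.
    """

    exposure_name: str
    variant_ids: list[str]
    provenance: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.variant_ids)


@dataclass
class HarmonizedSet:
    """Exposure/outcome effects aligned to one effect allele per variant."""

    variant_ids: list[str]
    beta_x: np.ndarray
    se_x: np.ndarray
    beta_y: np.ndarray
    se_y: np.ndarray
    eaf_x: np.ndarray
    eaf_y: np.ndarray
    n_exposure: int
    n_outcome: int
    exposure_name: str = "exposure"
    outcome_name: str = "outcome"
    dropped: dict[str, str] = field(default_factory=dict)
    proxies: dict[str, str] = field(default_factory=dict)  # original -> proxy

    def __post_init__(self) -> None:
        for name in ("beta_x", "se_x", "beta_y", "se_y", "eaf_x", "eaf_y"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        k = len(self.variant_ids)
        for name in ("beta_x", "se_x", "beta_y", "se_y"):
            if getattr(self, name).shape != (k,):
                raise InputError(f"{name} must have length {k}")
        overlap = set(self.variant_ids) & set(self.dropped)
        if overlap:
            raise InputError(f"variants both retained and dropped: {overlap}")

    @property
    def k(self) -> int:
        return len(self.variant_ids)

    def subset(self, keep: np.ndarray, dropped_reason: str | None = None) -> "HarmonizedSet":
        """Return a copy restricted to boolean/index mask ``keep``."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            idx = keep
        ids = [self.variant_ids[i] for i in idx]
        dropped = dict(self.dropped)
        if dropped_reason is not None:
            for v in self.variant_ids:
                if v not in ids:
                    dropped[v] = dropped_reason
        return replace(
            self,
            variant_ids=ids,
            beta_x=self.beta_x[idx], se_x=self.se_x[idx],
            beta_y=self.beta_y[idx], se_y=self.se_y[idx],
            eaf_x=self.eaf_x[idx], eaf_y=self.eaf_y[idx],
            dropped=dropped,
        )


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_sumstats(path, column_map: dict[str, str] | None = None,
                  trait_type: str = "continuous",
                  trait_name: str | None = None) -> SumStatTable:
    """Read a tab-separated summary-statistic table and validate each row.

    Rows failing record invariants (se <= 0, eaf outside (0,1), identical or
    non-ACGT alleles, p outside (0,1], p grossly inconsistent with |beta/se|)
    are dropped with a logged reason and count rather than aborting the read.

    Parameters
    ----------
    column_map
        Optional mapping from the file's column names to the canonical names
        ``variant_id, chrom, pos, effect_allele, other_allele, eaf, beta, se,
        pval, n``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in SUMSTAT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing mandatory column(s) {missing}")
    df = df[SUMSTAT_COLUMNS].copy()
    df["chrom"] = df["chrom"].astype(str)
    for col in ("eaf", "beta", "se", "pval"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.upper()

    reasons = pd.Series("", index=df.index, dtype=object)

    def _mark(mask, reason):
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    _mark(~(df["se"] > 0) | df["se"].isna(), "nonpositive_se")
    _mark(~df["eaf"].between(0, 1, inclusive="neither") | df["eaf"].isna(),
          "eaf_out_of_range")
    _mark(df["effect_allele"] == df["other_allele"], "degenerate_alleles")
    _mark(~df["effect_allele"].isin(list("ACGT"))
          | ~df["other_allele"].isin(list("ACGT")), "non_acgt_allele")
    _mark(~((df["pval"] > 0) & (df["pval"] <= 1)) | df["pval"].isna(),
          "pval_out_of_range")
    # gross beta/se vs p inconsistency (one order of magnitude on log10 p)
    ok = reasons == ""
    with np.errstate(divide="ignore"):
        derived = 2.0 * stats.norm.sf(np.abs(df["beta"] / df["se"]))
        lo_d = np.log10(np.maximum(derived, 1e-300))
        lo_s = np.log10(np.maximum(df["pval"].to_numpy(float), 1e-300))
    _mark(ok & (np.abs(lo_d - lo_s) > 1.0) & (pd.Series(derived, index=df.index) > 1e-290),
          "pval_inconsistent")

    bad = reasons != ""
    if bad.any():
        counts = reasons[bad].value_counts().to_dict()
        logger.warning("read_sumstats(%s): dropped %d row(s): %s",
                       path, int(bad.sum()), counts)
    df = df[~bad]
    if df.empty:
        raise EmptyInputError(f"{path}: no valid rows after validation")
    df = df.drop_duplicates(subset="variant_id", keep="first")
    df = df.set_index("variant_id", drop=False)
    df.index.name = None
    name = trait_name or str(path)
    return SumStatTable(trait_name=name, trait_type=trait_type, df=df)


def write_sumstats(table: SumStatTable, path) -> None:
    table.df[SUMSTAT_COLUMNS].to_csv(path, sep="\t", index=False)


def read_ld(path) -> LDMatrix:
    """Read a square LD-r matrix as TSV with variant ids as header + index."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise FormatError(f"{path}: LD row and column ids differ")
    return LDMatrix(variant_ids=[str(v) for v in df.columns],
                    r=df.to_numpy(float))


def write_ld(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.variant_ids, columns=ld.variant_ids).to_csv(
        path, sep="\t")


# ---------------------------------------------------------------------------
# instrument selection
# ---------------------------------------------------------------------------

def _parse_region(region) -> tuple[str, int, int]:
    if isinstance(region, str):
        try:
            chrom, span = region.split(":")
            start, end = span.split("-")
            return chrom, int(start), int(end)
        except ValueError as exc:
            raise InputError(f"malformed region {region!r}") from exc
    chrom, start, end = region
    return str(chrom), int(start), int(end)


def select_instruments(exposure: SumStatTable, ld: LDMatrix,
                       p_threshold: float = 5e-8,
                       clump_r2: float = 0.01,
                       clump_window_bp: int = 1_000_000,
                       exclude_regions=None) -> InstrumentSet:
    """Select genome-wide significant, approximately independent instruments.

    Candidates with p strictly below ``p_threshold`` are greedily clumped:
    sort ascending by p (ties broken by chrom, pos, variant_id so the result
    is invariant to input row order), retain the best, and remove every
    remaining candidate within ``clump_window_bp`` whose squared LD
    correlation with a retained variant exceeds ``clump_r2``.  Variants inside
    any 1-based inclusive span in ``exclude_regions`` are removed first with
    provenance ``removed:region_excluded``.
    """
    if not (0 < p_threshold < 1) or not (0 < clump_r2 < 1):
        raise InputError("p_threshold and clump_r2 must lie in (0,1)")
    provenance: dict[str, str] = {}
    cand = exposure.df[exposure.df["pval"] < p_threshold].copy()
    if cand.empty:
        raise EmptyInstrumentError(
            f"no variant in {exposure.trait_name} passes p < {p_threshold}")

    if exclude_regions:
        spans = [_parse_region(r) for r in exclude_regions]
        in_span = pd.Series(False, index=cand.index)
        for chrom, start, end in spans:
            in_span |= ((cand["chrom"] == chrom)
                        & (cand["pos"] >= start) & (cand["pos"] <= end))
        for v in cand.index[in_span]:
            provenance[v] = "removed:region_excluded"
        cand = cand[~in_span]
        if cand.empty:
            raise EmptyInstrumentError("all significant variants region-excluded")

    missing = [v for v in cand.index if v not in ld]
    if missing:
        raise VariantLookupError(
            f"candidate variant(s) absent from LD matrix: {missing[:5]}")

    cand = cand.sort_values(["pval", "chrom", "pos", "variant_id"],
                            kind="mergesort")
    retained: list[str] = []
    removed: set[str] = set()
    rows = cand[["chrom", "pos"]]
    for v in cand.index:
        if v in removed:
            continue
        retained.append(v)
        provenance[v] = "direct"
        chrom_v, pos_v = rows.at[v, "chrom"], rows.at[v, "pos"]
        near = cand.index[(rows["chrom"] == chrom_v)
                          & ((rows["pos"] - pos_v).abs() <= clump_window_bp)]
        for u in near:
            if u == v or u in removed or u in retained:
                continue
            if ld.r2_between(v, u) > clump_r2:
                removed.add(u)
                provenance[u] = "removed:ld_clump"
    return InstrumentSet(exposure_name=exposure.trait_name,
                         variant_ids=retained, provenance=provenance)


def find_proxy(variant_id: str, outcome: SumStatTable, ld: LDMatrix,
               min_r2: float = 0.8) -> str | None:
    """Best available stand-in for ``variant_id`` among the outcome's variants.

    Returns the outcome variant with the highest squared LD correlation to
    ``variant_id`` provided r² is strictly greater than ``min_r2``; otherwise
    ``None``.  Raises if the target variant is not covered by the LD matrix.
    """
    if not (0 < min_r2 < 1):
        raise InputError("min_r2 must lie in (0,1)")
    if variant_id not in ld:
        raise VariantLookupError(f"{variant_id} absent from LD matrix")
    best, best_r2 = None, 0.0
    for v in ld.variant_ids:
        if v not in outcome:
            continue
        r2 = ld.r2_between(variant_id, v)
        if r2 > best_r2:
            best, best_r2 = v, r2
    if best is not None and best_r2 > min_r2:
        return best
    return None


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

def _is_palindromic(a1: str, a2: str) -> bool:
    return _COMPLEMENT.get(a1) == a2


def harmonize(exposure: SumStatTable, outcome: SumStatTable,
              instruments: InstrumentSet,
              palindrome_eaf_limit: float = 0.42,
              ld: LDMatrix | None = None,
              proxy_min_r2: float = 0.8) -> HarmonizedSet:
    """Align exposure and outcome effects onto one effect allele per variant.

    Per variant: identical allele pair is kept as-is; a swapped pair negates
    the outcome beta (eaf -> 1-eaf); a complementary-strand pair is
    complemented first; palindromic variants (A/T, G/C) are aligned by
    allele-frequency concordance and dropped as ``palindromic_ambiguous``
    whenever either trait's minor-allele frequency exceeds
    ``palindrome_eaf_limit``; incompatible pairs are dropped.

    When an instrument is absent from the outcome table and ``ld`` is given,
    the best proxy with r² > ``proxy_min_r2`` substitutes for it: the proxy's
    outcome effect is re-signed by the LD correlation's sign, and the original
    variant's exposure record is kept.
    """
    if len(instruments) == 0:
        raise EmptyHarmonizationError("empty instrument set")

    ids, bx, sx, by, sy, fx, fy = [], [], [], [], [], [], []
    dropped: dict[str, str] = {}
    proxies: dict[str, str] = {}

    for v in instruments.variant_ids:
        ex = exposure.record(v)
        if v in outcome:
            out = outcome.record(v)
            aligned = _align_alleles(ex, out, palindrome_eaf_limit)
            if isinstance(aligned, str):
                dropped[v] = aligned
                continue
            b_out, se_out, eaf_out = aligned
        else:
            proxy = find_proxy(v, outcome, ld, proxy_min_r2) if ld is not None else None
            if proxy is None:
                dropped[v] = "missing_in_outcome"
                continue
            out = outcome.record(proxy)
            sign = np.sign(ld.r_between(v, proxy)) or 1.0
            b_out = sign * float(out["beta"])
            se_out = float(out["se"])
            eaf_out = float(out["eaf"]) if sign > 0 else 1.0 - float(out["eaf"])
            proxies[v] = proxy
        ids.append(v)
        bx.append(float(ex["beta"]))
        sx.append(float(ex["se"]))
        fx.append(float(ex["eaf"]))
        by.append(b_out)
        sy.append(se_out)
        fy.append(eaf_out)

    if not ids:
        raise EmptyHarmonizationError(
            f"all {len(instruments)} instrument(s) dropped: {dropped}")

    n_exp = int(np.median(exposure.df["n"]))
    n_out = int(np.median(outcome.df["n"]))
    return HarmonizedSet(
        variant_ids=ids,
        beta_x=bx, se_x=sx, beta_y=by, se_y=sy, eaf_x=fx, eaf_y=fy,
        n_exposure=n_exp, n_outcome=n_out,
        exposure_name=exposure.trait_name, outcome_name=outcome.trait_name,
        dropped=dropped, proxies=proxies)


def _align_alleles(ex: pd.Series, out: pd.Series, palindrome_eaf_limit: float):
    """Return (beta_y, se_y, eaf_y) aligned to the exposure's effect allele,
    or a drop-reason string."""
    ea_x, oa_x = ex["effect_allele"], ex["other_allele"]
    ea_y, oa_y = out["effect_allele"], out["other_allele"]
    beta_y, se_y, eaf_y = float(out["beta"]), float(out["se"]), float(out["eaf"])

    if _is_palindromic(ea_x, oa_x):
        if {ea_y, oa_y} != {ea_x, oa_x}:
            return "incompatible_alleles"
        eaf_x = float(ex["eaf"])
        maf_x = min(eaf_x, 1 - eaf_x)
        maf_y = min(eaf_y, 1 - eaf_y)
        if maf_x > palindrome_eaf_limit or maf_y > palindrome_eaf_limit:
            return "palindromic_ambiguous"
        if (eaf_x < 0.5) != (eaf_y < 0.5):
            return (-beta_y, se_y, 1 - eaf_y)
        return (beta_y, se_y, eaf_y)

    pair_y = (ea_y, oa_y)
    comp_y = (_COMPLEMENT.get(ea_y), _COMPLEMENT.get(oa_y))
    if pair_y == (ea_x, oa_x) or comp_y == (ea_x, oa_x):
        return (beta_y, se_y, eaf_y)
    if pair_y == (oa_x, ea_x) or comp_y == (oa_x, ea_x):
        return (-beta_y, se_y, 1 - eaf_y)
    return "incompatible_alleles"
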