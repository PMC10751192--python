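"""GWAS summary-statistic I/O, instrument selection and harmonization.

Summary statistics are exchanged as tab-separated tables with one row per
variant (columns ``SNP, CHR, POS, EA, OA, EAF, BETA, SE, P, N`` by default;
``NA`` encodes missing values).  Non-canonical headers are handled through a
*dialect* mapping from canonical field names to file column names.

Harmonization aligns the exposure and outcome association of each variant to
a shared effect allele, resolving strand complements and — by a configurable
policy — palindromic (A/T, G/C) variants whose strand cannot be read off the
alleles alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "SummaryStatRecord",
    "ManifestEntry",
    "InstrumentManifest",
    "HarmonizedInstrument",
    "ReadReport",
    "ProxyReport",
    "HarmonizeReport",
    "DEFAULT_DIALECT",
    "read_sumstats",
    "write_sumstats",
    "read_manifest",
    "substitute_proxies",
    "harmonize",
    "read_pleiotropy_flags",
    "apply_pleiotropy_filter",
]

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: Canonical field name -> default column header.
DEFAULT_DIALECT: dict[str, str] = {
    "snp_id": "SNP",
    "chrom": "CHR",
    "pos": "POS",
    "effect_allele": "EA",
    "other_allele": "OA",
    "eaf": "EAF",
    "beta": "BETA",
    "se": "SE",
    "pval": "P",
    "n": "N",
}

_MANDATORY_FIELDS = ("snp_id", "effect_allele", "other_allele", "beta", "se")


@dataclass(frozen=True)
class SummaryStatRecord:
    """Per-allele association of one variant in one GWAS.

    ``beta`` is the additive per-effect-allele effect (trait units for a
    quantitative trait, log-odds for a binary one); ``se`` its standard error.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    chrom: str | None = None
    pos: int | None = None
    eaf: float | None = None
    pval: float | None = None
    n: int | None = None

    def violations(self) -> list[str]:
        """Return the list of invariant violations (empty when valid)."""
        problems = []
        if self.effect_allele not in _VALID_ALLELES:
            problems.append("bad effect allele")
        if self.other_allele not in _VALID_ALLELES:
            problems.append("bad other allele")
        if (
            self.effect_allele in _VALID_ALLELES
            and self.effect_allele == self.other_allele
        ):
            problems.append("identical alleles")
        if not np.isfinite(self.beta):
            problems.append("non-finite beta")
        if not (np.isfinite(self.se) and self.se > 0):
            problems.append("non-positive se")
        if self.eaf is not None and not (0.0 <= self.eaf <= 1.0):
            problems.append("eaf outside [0,1]")
        if self.pval is not None and not (0.0 < self.pval <= 1.0):
            problems.append("pval outside (0,1]")
        if self.n is not None and self.n < 1:
            problems.append("n < 1")
        return problems

    @property
    def palindromic(self) -> bool:
        """True for A/T and C/G variants (strand-ambiguous)."""
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class ReadReport:
    """Row accounting for a summary-statistic read; silent loss is disallowed."""

    n_rows: int = 0
    n_valid: int = 0
    n_dropped: int = 0
    drop_reasons: dict[str, int] = field(default_factory=dict)


def read_sumstats(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> tuple[list[SummaryStatRecord], ReadReport]:
    """Read a summary-statistic TSV into records, dropping invalid rows.

    Parameters
    ----------
    path
        Tab-separated file with a header row; ``NA`` encodes missing.
    dialect
        Overrides of :data:`DEFAULT_DIALECT`, mapping canonical field names
        (``snp_id``, ``effect_allele`` ...) to the file's column headers.

    Returns
    -------
    (records, report)
        Valid records in file order plus a :class:`ReadReport` counting the
        rows dropped per reason.

    Raises
    ------
    ConfigurationError
        If a mandatory column cannot be resolved through the dialect.
    InputDataError
        If no valid rows remain.
    """
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect fields: {sorted(unknown)}")
        colmap.update(dialect)

    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={colmap["snp_id"]: str})
    missing = [colmap[f] for f in _MANDATORY_FIELDS if colmap[f] not in df.columns]
    if missing:
        raise ConfigurationError(
            f"mandatory column(s) {missing} not found in {path}; "
            f"available: {list(df.columns)}"
        )

    def _get(row, canonical, cast=None):
        col = colmap[canonical]
        if col not in df.columns:
            return None
        val = row[col]
        if pd.isna(val):
            return None
        return cast(val) if cast else val

    records: list[SummaryStatRecord] = []
    report = ReadReport(n_rows=len(df))
    for _, row in df.iterrows():
        rec = SummaryStatRecord(
            snp_id=str(row[colmap["snp_id"]]),
            effect_allele=str(row[colmap["effect_allele"]]).upper(),
            other_allele=str(row[colmap["other_allele"]]).upper(),
            beta=float(row[colmap["beta"]]) if pd.notna(row[colmap["beta"]]) else np.nan,
            se=float(row[colmap["se"]]) if pd.notna(row[colmap["se"]]) else np.nan,
            chrom=None if _get(row, "chrom") is None else str(_get(row, "chrom")),
            pos=_get(row, "pos", lambda v: int(float(v))),
            eaf=_get(row, "eaf", float),
            pval=_get(row, "pval", float),
            n=_get(row, "n", lambda v: int(float(v))),
        )
        problems = rec.violations()
        if problems:
            report.n_dropped += 1
            for p in problems:
                report.drop_reasons[p] = report.drop_reasons.get(p, 0) + 1
        else:
            records.append(rec)
    report.n_valid = len(records)
    if not records:
        raise InputDataError(f"no valid summary-statistic rows in {path}")
    return records, report


def write_sumstats(records: Iterable[SummaryStatRecord], path: str | Path) -> None:
    """Write records as a canonical-dialect TSV (missing fields as ``NA``)."""
    rows = []
    for r in records:
        rows.append(
            {
                "SNP": r.snp_id,
                "CHR": r.chrom,
                "POS": r.pos,
                "EA": r.effect_allele,
                "OA": r.other_allele,
                "EAF": r.eaf,
                "BETA": r.beta,
                "SE": r.se,
                "P": r.pval,
                "N": r.n,
            }
        )
    pd.DataFrame(rows, columns=list(DEFAULT_DIALECT.values())).to_csv(
        path, sep="\t", index=False, na_rep="NA"
    )


# ---------------------------------------------------------------------------
# Instrument manifest and proxy substitution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ManifestEntry:
    lead_snp: str
    available: bool
    proxy_snp: str | None = None
    ld_r2: float | None = None
    ld_dprime: float | None = None

    def __post_init__(self):
        if self.available and self.proxy_snp is not None:
            raise InputDataError(
                f"{self.lead_snp}: proxy listed for an available lead SNP"
            )
        if (self.ld_r2 is not None) != (self.proxy_snp is not None):
            raise InputDataError(f"{self.lead_snp}: ld_r2 present iff proxy present")


@dataclass
class InstrumentManifest:
    """Lead-SNP availability and proxy mapping for the instrument set."""

    entries: list[ManifestEntry]


@dataclass
class ProxyReport:
    n_leads: int
    n_available: int
    n_proxied: int
    dropped: list[str]
    proxied: dict[str, str]  # lead -> proxy
    ld_r2: dict[str, float]


def read_manifest(path: str | Path) -> InstrumentManifest:
    """Read a manifest TSV (columns LEAD_SNP, AVAILABLE, PROXY_SNP, R2, DPRIME)."""
    df = pd.read_csv(path, sep="\t", na_values=["NA"], dtype={"LEAD_SNP": str})
    required = {"LEAD_SNP", "AVAILABLE"}
    if not required <= set(df.columns):
        raise ConfigurationError(f"manifest must contain columns {sorted(required)}")
    entries = []
    for _, row in df.iterrows():
        entries.append(
            ManifestEntry(
                lead_snp=str(row["LEAD_SNP"]),
                available=bool(int(row["AVAILABLE"])),
                proxy_snp=None if pd.isna(row.get("PROXY_SNP")) else str(row["PROXY_SNP"]),
                ld_r2=None if pd.isna(row.get("R2")) else float(row["R2"]),
                ld_dprime=None if pd.isna(row.get("DPRIME")) else float(row["DPRIME"]),
            )
        )
    return InstrumentManifest(entries)


def substitute_proxies(manifest: InstrumentManifest) -> tuple[list[str], ProxyReport]:
    """Resolve the usable instrument ids from a lead-SNP manifest.

    Available leads are kept; unavailable leads are replaced by their proxy
    when one is listed, and dropped (with accounting) otherwise.  LD metrics
    are carried through to the report but not thresholded: proxy acceptance
    is the manifest author's call.
    """
    if not manifest.entries:
        raise InputDataError("empty instrument manifest")
    ids: list[str] = []
    report = ProxyReport(
        n_leads=len(manifest.entries),
        n_available=0,
        n_proxied=0,
        dropped=[],
        proxied={},
        ld_r2={},
    )
    for e in manifest.entries:
        if e.available:
            ids.append(e.lead_snp)
            report.n_available += 1
        elif e.proxy_snp is not None:
            ids.append(e.proxy_snp)
            report.n_proxied += 1
            report.proxied[e.lead_snp] = e.proxy_snp
            if e.ld_r2 is not None:
                report.ld_r2[e.lead_snp] = e.ld_r2
        else:
            report.dropped.append(e.lead_snp)
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise InputDataError(f"duplicate instrument ids after substitution: {sorted(dup)}")
    return ids, report


# ---------------------------------------------------------------------------
# Harmonization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HarmonizedInstrument:
    """One instrument with exposure (gamma) and outcome (Gamma) effects on a
    shared effect allele."""

    snp_id: str
    gamma: float
    se_gamma: float
    Gamma: float
    se_Gamma: float
    flipped: bool = False
    palindromic: bool = False


@dataclass
class HarmonizeReport:
    n_exposure: int = 0
    n_matched: int = 0
    n_harmonized: int = 0
    dropped: dict[str, str] = field(default_factory=dict)  # snp_id -> reason


PALINDROMIC_POLICIES = ("drop", "infer-by-frequency", "keep-as-is")

#: EAFs inside this window are too close to 0.5 to orient a palindromic SNP.
AMBIGUOUS_EAF_WINDOW = (0.42, 0.58)
#: Max |EAF difference| for two palindromic records to count as same-orientation.
EAF_MATCH_TOL = 0.2


def _orient(outcome: SummaryStatRecord, ea: str, oa: str) -> tuple[float, bool] | None:
    """Outcome beta on effect allele ``ea``, or None when alleles don't fit."""
    if (outcome.effect_allele, outcome.other_allele) == (ea, oa):
        return outcome.beta, False
    if (outcome.effect_allele, outcome.other_allele) == (oa, ea):
        return -outcome.beta, True
    return None


def harmonize(
    exposure: Sequence[SummaryStatRecord],
    outcome: Sequence[SummaryStatRecord],
    palindromic_policy: str = "infer-by-frequency",
) -> tuple[list[HarmonizedInstrument], HarmonizeReport]:
    """Align exposure and outcome records to the exposure effect allele.

    Variants are matched by rsID.  Swapped alleles flip the sign of the
    outcome beta; strand complements are resolved by complementing the outcome
    alleles first.  Palindromic variants, for which complementing is a no-op,
    are handled per ``palindromic_policy``:

    ``drop``
        discard them;
    ``infer-by-frequency`` (default)
        orient so the two effect-allele frequencies agree (within
        :data:`EAF_MATCH_TOL`); usable only when both EAFs are present and
        both fall outside the ambiguity window
        :data:`AMBIGUOUS_EAF_WINDOW`, else the variant is dropped;
    ``keep-as-is``
        trust that both panels report the same strand.
    """
    if palindromic_policy not in PALINDROMIC_POLICIES:
        raise ConfigurationError(
            f"palindromic_policy must be one of {PALINDROMIC_POLICIES}"
        )
    by_id = {r.snp_id: r for r in outcome}
    out: list[HarmonizedInstrument] = []
    report = HarmonizeReport(n_exposure=len(exposure))
    for exp in exposure:
        rec = by_id.get(exp.snp_id)
        if rec is None:
            report.dropped[exp.snp_id] = "not in outcome"
            continue
        report.n_matched += 1
        ea, oa = exp.effect_allele, exp.other_allele

        if exp.palindromic:
            if palindromic_policy == "drop":
                report.dropped[exp.snp_id] = "palindromic"
                continue
            oriented = _orient(rec, ea, oa)
            if oriented is None:
                report.dropped[exp.snp_id] = "allele mismatch"
                continue
            beta, flipped = oriented
            if palindromic_policy == "infer-by-frequency":
                lo, hi = AMBIGUOUS_EAF_WINDOW
                if exp.eaf is None or rec.eaf is None:
                    report.dropped[exp.snp_id] = "palindromic: missing eaf"
                    continue
                out_eaf = 1.0 - rec.eaf if flipped else rec.eaf
                if lo <= exp.eaf <= hi or lo <= out_eaf <= hi:
                    report.dropped[exp.snp_id] = "palindromic: ambiguous eaf"
                    continue
                if abs(exp.eaf - out_eaf) <= EAF_MATCH_TOL:
                    pass  # orientation consistent with frequencies
                elif abs(exp.eaf - (1.0 - out_eaf)) <= EAF_MATCH_TOL:
                    # frequencies say the panels are on opposite strands
                    beta, flipped = -beta, not flipped
                else:
                    report.dropped[exp.snp_id] = "palindromic: eaf mismatch"
                    continue
            out.append(
                HarmonizedInstrument(
                    exp.snp_id, exp.beta, exp.se, beta, rec.se,
                    flipped=flipped, palindromic=True,
                )
            )
            continue

        oriented = _orient(rec, ea, oa)
        if oriented is None:
            # try the complementary strand
            comp = SummaryStatRecord(
                rec.snp_id,
                _COMPLEMENT[rec.effect_allele],
                _COMPLEMENT[rec.other_allele],
                rec.beta,
                rec.se,
                eaf=rec.eaf,
            )
            oriented = _orient(comp, ea, oa)
        if oriented is None:
            report.dropped[exp.snp_id] = "allele mismatch"
            continue
        beta, flipped = oriented
        out.append(
            HarmonizedInstrument(
                exp.snp_id, exp.beta, exp.se, beta, rec.se,
                flipped=flipped, palindromic=False,
            )
        )
    report.n_harmonized = len(out)
    return out, report


# ---------------------------------------------------------------------------
# Pleiotropy-flag sensitivity filter
# ---------------------------------------------------------------------------

#: Secondary traits a BMI instrument may be flagged for.
PLEIOTROPY_TRAITS = frozenset(
    {"T2D", "SBP", "DBP", "TG", "TC", "HDL", "LDL", "UA", "eGFR", "HbA1c", "CAD", "IS"}
)

PleiotropyFlagTable = dict[str, set[str]]


def read_pleiotropy_flags(path: str | Path) -> PleiotropyFlagTable:
    """Read a SNP/TRAIT TSV into a mapping snp_id -> set of trait labels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"SNP", "TRAIT"} <= set(df.columns):
        raise ConfigurationError("pleiotropy flag table needs columns SNP, TRAIT")
    table: PleiotropyFlagTable = {}
    for _, row in df.iterrows():
        trait = row["TRAIT"]
        if trait not in PLEIOTROPY_TRAITS:
            raise InputDataError(f"unknown secondary-trait label {trait!r}")
        table.setdefault(row["SNP"], set()).add(trait)
    return table


def apply_pleiotropy_filter(
    instruments: Sequence[HarmonizedInstrument],
    flags: PleiotropyFlagTable,
) -> list[HarmonizedInstrument]:
    """Drop instruments flagged for association with a secondary trait.

    This is the sensitivity analysis that removes variants with genome-wide
    significant associations to other cardiometabolic traits, so the retained
    set carries less known horizontal pleiotropy.  Order is preserved.
    """
    return [i for i in instruments if i.snp_id not in flags]
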