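"""Proximity-based GWAS colocalization.

Two sets of genome-wide-significant SNPs (a "catalog" side, e.g. an
NHGRI-EBI association export, and a "biobank" side, e.g. in-house GWAS hits)
are joined on chromosome with a base-pair window: every (catalog, biobank)
pair on the same chromosome with |position difference| <= 50 kb (inclusive;
both sides on GRCh38) is a candidate shared locus.  Per catalog anchor SNP
the pairings are counted, annotated with gene symbols from a local map, and
reported only when the count reaches a threshold.

This is deliberately *not* a posterior-probability colocalization method:
no LD, no effect sizes, just significance filtering and genomic proximity.

The join runs as a per-chromosome sort plus two-pointer sweep, near-linear
in the number of SNPs; a brute-force all-pairs scan over small instances is
the reference oracle in the test suite.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

GENOME_WIDE_ALPHA = 5e-8
DEFAULT_WINDOW_BP = 50_000

_VALID_CHROMS = {str(i) for i in range(1, 23)} | {"X", "Y", "MT"}

# NHGRI-EBI GWAS Catalog association-export column names -> native names
_CATALOG_COLUMNS = {
    "SNPS": "rsid",
    "CHR_ID": "chrom",
    "CHR_POS": "pos",
    "P-VALUE": "pvalue",
    "DISEASE/TRAIT": "trait",
}
_NATIVE_COLUMNS = ["rsid", "chrom", "pos", "pvalue", "trait"]


@dataclass(frozen=True)
class GwasSnp:
    """One genome-wide-significant association."""

    rsid: str
    chromosome: str
    position: int  # 1-based, GRCh38
    p_value: float
    trait: str
    side: str = "catalog"  # {catalog, biobank}

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError(f"position must be >= 1, got {self.position}")
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.chromosome not in _VALID_CHROMS:
            raise ValueError(f"invalid chromosome label {self.chromosome!r}")


@dataclass(frozen=True)
class SnpPair:
    catalog_snp: GwasSnp
    biobank_snp: GwasSnp

    @property
    def distance(self) -> int:
        return abs(self.catalog_snp.position - self.biobank_snp.position)


@dataclass
class ReadDiagnostics:
    n_rows: int = 0
    n_skipped: int = 0


def normalize_chromosome(label) -> str | None:
    """Strip 'chr' prefixes, uppercase; return None if not a valid label."""
    s = str(label).strip().upper()
    if s.startswith("CHR"):
        s = s[3:]
    if s == "M":
        s = "MT"
    if s in {"23", "24", "25"}:  # PLINK-style numeric sex/mito codes
        s = {"23": "X", "24": "Y", "25": "MT"}[s]
    return s if s in _VALID_CHROMS else None


def read_summary_stats(
    path: str | Path,
    dialect: str = "native",
    side: str = "catalog",
    diagnostics: ReadDiagnostics | None = None,
) -> list[GwasSnp]:
    """Read a tab-delimited summary-statistic file into GwasSnp records.

    ``native`` expects columns rsid/chrom/pos/pvalue/trait; ``catalog_tsv``
    expects the GWAS Catalog association-export names (SNPS, CHR_ID,
    CHR_POS, P-VALUE, DISEASE/TRAIT).  Rows whose chromosome or position do
    not parse (e.g. "NR", multi-mapping entries) are skipped and counted.
    Scientific-notation p-values are accepted.
    """
    diag = diagnostics if diagnostics is not None else ReadDiagnostics()
    if dialect == "native":
        colmap = {c: c for c in _NATIVE_COLUMNS}
    elif dialect == "catalog_tsv":
        colmap = _CATALOG_COLUMNS
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    snps: list[GwasSnp] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        header = reader.fieldnames or []
        missing = [c for c in colmap if c not in header]
        if missing:
            raise ValueError(f"missing required column(s) {missing} for dialect {dialect!r}")
        for row in reader:
            diag.n_rows += 1
            chrom = normalize_chromosome(row[_key(colmap, "chrom")])
            try:
                pos = int(str(row[_key(colmap, "pos")]).strip())
                pval = float(str(row[_key(colmap, "pvalue")]).strip())
            except (ValueError, TypeError):
                diag.n_skipped += 1
                continue
            if chrom is None or pos < 1 or not (0 < pval <= 1):
                diag.n_skipped += 1
                continue
            snps.append(
                GwasSnp(
                    rsid=str(row[_key(colmap, "rsid")]).strip(),
                    chromosome=chrom,
                    position=pos,
                    p_value=pval,
                    trait=str(row[_key(colmap, "trait")]).strip(),
                    side=side,
                )
            )
    return snps


def _key(colmap: dict[str, str], native: str) -> str:
    return next(k for k, v in colmap.items() if v == native)


def filter_significant(snps: list[GwasSnp], alpha: float = GENOME_WIDE_ALPHA) -> list[GwasSnp]:
    """Retain exactly the SNPs with p strictly below the genome-wide
    threshold (p = alpha itself is removed); input order preserved."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return [s for s in snps if s.p_value < alpha]


def _dedupe(snps: list[GwasSnp]) -> list[GwasSnp]:
    seen: set[tuple] = set()
    out = []
    for s in snps:
        key = (s.rsid, s.trait, s.side)
        if key not in seen:
            seen.add(key)
            out.append(s)
    return out


def window_join(
    catalog: list[GwasSnp], biobank: list[GwasSnp], window_bp: int = DEFAULT_WINDOW_BP
) -> list[SnpPair]:
    """All (catalog, biobank) pairs on the same chromosome within the window.

    The distance bound is inclusive (|delta pos| <= window_bp).  Duplicate
    input records (same rsid+trait+side) are dropped before joining, so the
    result is invariant under input permutation and duplication.  Output is
    deterministically sorted by (chromosome, catalog position, biobank
    position, rsids).
    """
    if window_bp < 0:
        raise ValueError("window_bp must be >= 0")
    cat = _dedupe(catalog)
    bio = _dedupe(biobank)
    by_chrom: dict[str, list[GwasSnp]] = {}
    for s in bio:
        by_chrom.setdefault(s.chromosome, []).append(s)
    for chrom in by_chrom:
        by_chrom[chrom].sort(key=lambda s: (s.position, s.rsid, s.trait))

    pairs: list[SnpPair] = []
    for c in cat:
        cand = by_chrom.get(c.chromosome)
        if not cand:
            continue
        positions = [s.position for s in cand]
        lo = int(np.searchsorted(positions, c.position - window_bp, side="left"))
        hi = int(np.searchsorted(positions, c.position + window_bp, side="right"))
        for b in cand[lo:hi]:
            pairs.append(SnpPair(catalog_snp=c, biobank_snp=b))
    pairs.sort(
        key=lambda p: (
            _chrom_sort_key(p.catalog_snp.chromosome),
            p.catalog_snp.position,
            p.biobank_snp.position,
            p.catalog_snp.rsid,
            p.biobank_snp.rsid,
            p.catalog_snp.trait,
            p.biobank_snp.trait,
        )
    )
    return pairs


def _chrom_sort_key(label: str) -> tuple[int, str]:
    return (0, f"{int(label):02d}") if label.isdigit() else (1, label)


def count_pairings(pairs: list[SnpPair], count_key: str = "rsid_trait") -> pd.DataFrame:
    """Per-anchor pairing report.

    For each catalog rsid: the deduplicated (order-preserving) catalog and
    biobank trait lists and the pairing count.  With the default
    ``rsid_trait`` convention the count is the number of distinct
    (biobank rsid, biobank trait) records paired with the anchor, so one
    biobank SNP significant for two traits contributes two pairings;
    ``rsid`` collapses trait multiplicity.  Summed over anchors, the
    default counts conserve the number of distinct pair records.
    """
    if count_key not in ("rsid_trait", "rsid"):
        raise ValueError(f"unknown count_key {count_key!r}")
    report: dict[str, dict] = {}
    for p in pairs:
        row = report.setdefault(
            p.catalog_snp.rsid,
            {"catalog_rsid": p.catalog_snp.rsid, "catalog_traits": [], "biobank_traits": [],
             "_records": set()},
        )
        if p.catalog_snp.trait not in row["catalog_traits"]:
            row["catalog_traits"].append(p.catalog_snp.trait)
        if p.biobank_snp.trait not in row["biobank_traits"]:
            row["biobank_traits"].append(p.biobank_snp.trait)
        rec = (p.biobank_snp.rsid, p.biobank_snp.trait) if count_key == "rsid_trait" else p.biobank_snp.rsid
        row["_records"].add(rec)
    rows = []
    for rsid, row in report.items():
        rows.append(
            {
                "catalog_rsid": rsid,
                "catalog_traits": ", ".join(row["catalog_traits"]),
                "biobank_traits": ", ".join(row["biobank_traits"]),
                "n_pairings": len(row["_records"]),
            }
        )
    return pd.DataFrame(rows, columns=["catalog_rsid", "catalog_traits", "biobank_traits", "n_pairings"])


def unique_pair_count(pairs: list[SnpPair]) -> int:
    """Number of distinct (catalog rsid, biobank rsid) combinations,
    collapsing trait multiplicity."""
    return len({(p.catalog_snp.rsid, p.biobank_snp.rsid) for p in pairs})


def load_gene_map(path: str | Path) -> dict[str, str]:
    """rsid -> comma-separated gene symbols, from a two-column TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise ValueError("gene map TSV needs at least two columns (rsid, genes)")
    rsid_col, gene_col = df.columns[0], df.columns[1]
    return dict(zip(df[rsid_col].astype(str), df[gene_col].astype(str)))


def annotate_and_filter(
    report: pd.DataFrame, gene_map: dict[str, str], min_pairings: int = 3
) -> pd.DataFrame:
    """Drop anchors with fewer than ``min_pairings`` pairings (default 3,
    i.e. only anchors with more than 2 pairings are reported), attach gene
    symbols ("NA" when unmapped), and sort by descending count then rsid."""
    out = report[report["n_pairings"] >= min_pairings].copy()
    out["genes"] = out["catalog_rsid"].map(lambda r: gene_map.get(r, "NA"))
    out = out.sort_values(
        ["n_pairings", "catalog_rsid"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return out


def pairs_to_frame(pairs: list[SnpPair]) -> pd.DataFrame:
    """Tabular view of a pair list (the pairs TSV layout)."""
    return pd.DataFrame(
        [
            {
                "catalog_rsid": p.catalog_snp.rsid,
                "biobank_rsid": p.biobank_snp.rsid,
                "chrom": p.catalog_snp.chromosome,
                "catalog_pos": p.catalog_snp.position,
                "biobank_pos": p.biobank_snp.position,
                "distance": p.distance,
                "catalog_trait": p.catalog_snp.trait,
                "biobank_trait": p.biobank_snp.trait,
            }
            for p in pairs
        ],
        columns=[
            "catalog_rsid", "biobank_rsid", "chrom", "catalog_pos", "biobank_pos",
            "distance", "catalog_trait", "biobank_trait",
        ],
    )
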