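"""Variant panel, genotype ingestion, region extraction, and variant QC.

The panel is a table of risk-designated biallelic SNPs (rsid, position,
ref/alt, risk allele, gene).  Genotypes arrive as a VCF; coordinates are
1-based inclusive everywhere (VCF convention).  Chromosome names are
normalized by stripping a leading ``chr``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

Call = tuple[str, str]  # unphased diploid genotype, alphabetically ordered


class PanelError(ValueError):
    pass


def norm_chrom(chrom: str) -> str:
    c = str(chrom)
    return c[3:] if c.lower().startswith("chr") else c


# ---------------------------------------------------------------------------
# Gene regions
# ---------------------------------------------------------------------------

#: GRCh37 coordinates of the six late-onset Alzheimer's disease candidate
#: genes scored by the burden pipeline.
DEFAULT_REGIONS: dict[str, tuple[str, int, int]] = {
    "APOE": ("19", 45_409_011, 45_412_650),
    "PICALM": ("11", 85_673_738, 85_782_667),
    "CLU": ("8", 27_453_434, 27_469_869),
    "CR1": ("1", 207_494_290, 207_667_439),
    "BIN1": ("2", 127_803_005, 127_897_976),
    "ABCA7": ("19", 1_040_673, 1_084_340),
}


def default_regions() -> pd.DataFrame:
    """The six candidate-gene regions as a gene/chrom/start/end table."""
    rows = [
        {"gene": g, "chrom": c, "start": s, "end": e}
        for g, (c, s, e) in DEFAULT_REGIONS.items()
    ]
    return pd.DataFrame(rows, columns=["gene", "chrom", "start", "end"])


def load_regions(path: str | Path) -> pd.DataFrame:
    """Load a gene-region TSV (columns gene, chrom, start, end; 1-based inclusive)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"gene", "chrom", "start", "end"} - set(df.columns)
    if missing:
        raise PanelError(f"region table missing columns: {sorted(missing)}")
    df = df[["gene", "chrom", "start", "end"]].copy()
    df["chrom"] = df["chrom"].map(norm_chrom)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] > df["end"]).any():
        bad = df.loc[df["start"] > df["end"], "gene"].tolist()
        raise PanelError(f"start > end for gene(s) {bad}")
    if df["gene"].duplicated().any():
        dup = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise PanelError(f"duplicate gene(s) in region table: {dup}")
    return df.reset_index(drop=True)


def write_regions(regions: pd.DataFrame, path: str | Path) -> None:
    regions.to_csv(path, sep="\t", index=False)


def region_length(regions: pd.DataFrame, gene: str) -> int:
    row = regions.loc[regions["gene"] == gene]
    if row.empty:
        raise PanelError(f"gene {gene!r} not in region table")
    return int(row["end"].iloc[0] - row["start"].iloc[0] + 1)


# ---------------------------------------------------------------------------
# Variant panel
# ---------------------------------------------------------------------------

PANEL_COLUMNS = ["rsid", "chrom", "pos", "ref", "alt", "risk_allele", "gene", "source"]


@dataclass(frozen=True)
class VariantRecord:
    rsid: str
    chrom: str
    pos: int
    ref: str
    alt: str
    risk_allele: str
    gene: str
    source: str = ""

    @property
    def biallelic(self) -> bool:
        return "," not in self.alt

    @property
    def has_risk_designation(self) -> bool:
        return self.risk_allele in (self.ref, self.alt) and self.biallelic


class VariantPanel:
    """Ordered collection of risk-designated SNP records."""

    def __init__(self, records: Iterable[VariantRecord]):
        self.records: list[VariantRecord] = list(records)
        seen: set[str] = set()
        for r in self.records:
            if r.rsid in seen:
                raise PanelError(f"duplicate rsid {r.rsid!r} in panel")
            seen.add(r.rsid)
        self._by_rsid = {r.rsid: r for r in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantRecord]:
        return iter(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._by_rsid

    def __getitem__(self, rsid: str) -> VariantRecord:
        return self._by_rsid[rsid]

    @property
    def rsids(self) -> list[str]:
        return [r.rsid for r in self.records]

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.gene not in out:
                out.append(r.gene)
        return out

    def per_gene_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.gene] = counts.get(r.gene, 0) + 1
        return counts

    def subset(self, rsids: Iterable[str]) -> "VariantPanel":
        keep = set(rsids)
        return VariantPanel(r for r in self.records if r.rsid in keep)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records], columns=PANEL_COLUMNS)

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def load_panel(path: str | Path) -> VariantPanel:
    """Load a panel TSV (rsid, chrom, pos, ref, alt, risk_allele, gene, source).

    Records with an invalid or absent risk-allele designation are loaded as-is;
    :func:`apply_qc_filters` removes them (rule 2).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(PANEL_COLUMNS[:-1]) - set(df.columns)
    if missing:
        raise PanelError(f"panel missing columns: {sorted(missing)}")
    records = [
        VariantRecord(
            rsid=row.rsid,
            chrom=norm_chrom(row.chrom),
            pos=int(row.pos),
            ref=row.ref,
            alt=row.alt,
            risk_allele=row.risk_allele,
            gene=row.gene,
            source=getattr(row, "source", ""),
        )
        for row in df.itertuples()
    ]
    return VariantPanel(records)


# ---------------------------------------------------------------------------
# Genotype matrix
# ---------------------------------------------------------------------------


class GenotypeMatrix:
    """Per (sample, snp) unphased diploid calls; ``None`` marks a missing call."""

    def __init__(
        self,
        samples: Sequence[str],
        rsids: Sequence[str],
        calls: np.ndarray | None = None,
        multiallelic: Iterable[str] = (),
    ):
        self.samples = list(samples)
        self.rsids = list(rsids)
        self.sample_index = {s: i for i, s in enumerate(self.samples)}
        self.rsid_index = {r: j for j, r in enumerate(self.rsids)}
        if len(self.sample_index) != len(self.samples):
            raise PanelError("duplicate sample ids")
        if len(self.rsid_index) != len(self.rsids):
            raise PanelError("duplicate rsids")
        if calls is None:
            calls = np.full((len(self.samples), len(self.rsids)), None, dtype=object)
        if calls.shape != (len(self.samples), len(self.rsids)):
            raise PanelError("calls shape inconsistent with samples/rsids")
        self.calls = calls
        self.multiallelic = set(multiallelic)

    def call(self, sample: str, rsid: str) -> Call | None:
        return self.calls[self.sample_index[sample], self.rsid_index[rsid]]

    def set_call(self, sample: str, rsid: str, call: Call | None) -> None:
        if call is not None:
            call = tuple(sorted(call))  # type: ignore[assignment]
        self.calls[self.sample_index[sample], self.rsid_index[rsid]] = call

    def is_missing(self, sample: str, rsid: str) -> bool:
        return self.call(sample, rsid) is None

    def column(self, rsid: str) -> list[Call | None]:
        j = self.rsid_index[rsid]
        return list(self.calls[:, j])

    def subset_samples(self, samples: Sequence[str]) -> "GenotypeMatrix":
        idx = [self.sample_index[s] for s in samples]
        return GenotypeMatrix(
            samples, self.rsids, self.calls[idx, :].copy(), self.multiallelic
        )

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(
            self.samples, self.rsids, self.calls.copy(), set(self.multiallelic)
        )

    def equals(self, other: "GenotypeMatrix") -> bool:
        return (
            self.samples == other.samples
            and self.rsids == other.rsids
            and all(
                self.calls[i, j] == other.calls[i, j]
                for i in range(len(self.samples))
                for j in range(len(self.rsids))
            )
        )


def load_genotypes(path: str | Path, samples: Sequence[str] | None = None) -> GenotypeMatrix:
    """Read GT calls from a VCF into a :class:`GenotypeMatrix`.

    Multi-allelic records are passed through and flagged (removed later by QC
    rule 1); ``./.`` becomes a missing call.  Records without an ID are
    skipped (the panel is rsid-keyed).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    header_samples = list(vcf.samples)
    if samples is None:
        samples = header_samples
    else:
        absent = [s for s in samples if s not in header_samples]
        if absent:
            raise PanelError(f"sample(s) {absent} absent from VCF header")
    col = {s: header_samples.index(s) for s in samples}
    rsids: list[str] = []
    rows: list[list[Call | None]] = []
    multi: set[str] = set()
    for v in vcf:
        rid = v.ID
        if rid is None or rid == ".":
            continue
        if len(v.ALT) > 1:
            multi.add(rid)
        rsids.append(rid)
        bases = v.gt_bases  # e.g. "A/G", "./."
        row: list[Call | None] = []
        for s in samples:
            gt = bases[col[s]].replace("|", "/")
            alleles = gt.split("/")
            if "." in alleles or len(alleles) != 2:
                row.append(None)
            else:
                row.append(tuple(sorted(alleles)))  # type: ignore[arg-type]
        rows.append(row)
    calls = np.empty((len(samples), len(rsids)), dtype=object)
    for j, row in enumerate(rows):
        for i, c in enumerate(row):
            calls[i, j] = c
    return GenotypeMatrix(list(samples), rsids, calls, multi)


def write_vcf(gm: GenotypeMatrix, panel: VariantPanel, path: str | Path) -> None:
    """Write panel snps + calls as an uncompressed VCFv4.2 file (sorted)."""

    def sort_key(r: VariantRecord) -> tuple[int, str, int]:
        c = r.chrom
        return (0, f"{int(c):02d}", r.pos) if c.isdigit() else (1, c, r.pos)

    records = sorted((panel[r] for r in gm.rsids if r in panel), key=sort_key)
    lines = ["##fileformat=VCFv4.2", "##source=famburden"]
    seen_chroms: list[str] = []
    for r in records:
        if r.chrom not in seen_chroms:
            seen_chroms.append(r.chrom)
    for c in seen_chroms:
        lines.append(f"##contig=<ID={c}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(gm.samples))
    for r in records:
        allele_idx = {r.ref: "0", r.alt: "1"}
        gts = []
        for s in gm.samples:
            call = gm.call(s, r.rsid)
            if call is None:
                gts.append("./.")
            else:
                gts.append("/".join(sorted(allele_idx[a] for a in call)))
        lines.append(
            f"{r.chrom}\t{r.pos}\t{r.rsid}\t{r.ref}\t{r.alt}\t.\t.\t.\tGT\t" + "\t".join(gts)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def merge_direct_genotypes(gm: GenotypeMatrix, path: str | Path) -> GenotypeMatrix:
    """Merge a side TSV of directly assayed genotypes (sample_id, rsid, gt).

    Covers snps absent from the array VCF (e.g. the two epsilon-defining APOE
    snps).  When a call is present in both sources it must agree.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = {"sample_id", "rsid", "gt"} - set(df.columns)
    if missing:
        raise PanelError(f"direct-genotype TSV missing columns: {sorted(missing)}")
    new_rsids = [r for r in df["rsid"].unique() if r not in gm.rsid_index]
    out = GenotypeMatrix(
        gm.samples,
        gm.rsids + new_rsids,
        np.concatenate(
            [gm.calls, np.full((len(gm.samples), len(new_rsids)), None, dtype=object)],
            axis=1,
        ),
        gm.multiallelic,
    )
    for row in df.itertuples():
        if row.sample_id not in out.sample_index:
            continue
        call = tuple(sorted(str(row.gt).replace("|", "/").split("/")))
        if len(call) != 2:
            raise PanelError(f"bad genotype {row.gt!r} for {row.sample_id}/{row.rsid}")
        existing = out.call(row.sample_id, row.rsid)
        if existing is not None and existing != call:
            raise PanelError(
                f"direct genotype disagrees with VCF for {row.sample_id}/{row.rsid}: "
                f"{existing} vs {call}"
            )
        out.set_call(row.sample_id, row.rsid, call)  # type: ignore[arg-type]
    return out


# ---------------------------------------------------------------------------
# Region extraction and QC
# ---------------------------------------------------------------------------


def _flanked(regions: pd.DataFrame, flank_bp: int) -> list[tuple[str, int, int, str]]:
    out = [
        (norm_chrom(row.chrom), int(row.start) - flank_bp, int(row.end) + flank_bp, row.gene)
        for row in regions.itertuples()
    ]
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for c, s, e, g in out:
        by_chrom.setdefault(c, []).append((s, e, g))
    for c, ivals in by_chrom.items():
        ivals.sort()
        for (s1, e1, g1), (s2, e2, g2) in zip(ivals, ivals[1:]):
            if s2 <= e1:
                raise PanelError(
                    f"flanked regions overlap on chromosome {c}: {g1} and {g2}"
                )
    return out


def extract_region_variants(
    panel: VariantPanel, regions: pd.DataFrame, flank_bp: int = 50_000
) -> VariantPanel:
    """Keep panel records inside a candidate-gene region ± ``flank_bp``.

    Boundaries are inclusive; the record's gene label is reassigned to the
    matching region.  Flanked regions must not overlap on a chromosome.
    """
    if flank_bp < 0:
        raise PanelError("flank_bp must be >= 0")
    windows = _flanked(regions, flank_bp)
    kept: list[VariantRecord] = []
    for r in panel:
        for c, s, e, g in windows:
            if r.chrom == c and s <= r.pos <= e:
                if r.gene != g:
                    r = VariantRecord(
                        r.rsid, r.chrom, r.pos, r.ref, r.alt, r.risk_allele, g, r.source
                    )
                kept.append(r)
                break
    return VariantPanel(kept)


QC_RULES = ("multiallelic", "no_risk_designation", "monomorphic", "missing_calls")


@dataclass
class QCReport:
    """Per-rule removal counts and rsids; rules applied in the listed order."""

    removed: dict[str, list[str]] = field(
        default_factory=lambda: {rule: [] for rule in QC_RULES}
    )
    survivors: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {rule: len(v) for rule, v in self.removed.items()}

    @property
    def n_input(self) -> int:
        return len(self.survivors) + sum(self.counts.values())

    def to_tsv(self, path: str | Path) -> None:
        lines = ["rule\tn_removed\trsids"]
        for rule in QC_RULES:
            lines.append(f"{rule}\t{len(self.removed[rule])}\t{','.join(self.removed[rule])}")
        lines.append(f"survivors\t{len(self.survivors)}\t{','.join(self.survivors)}")
        Path(path).write_text("\n".join(lines) + "\n")


def apply_qc_filters(panel: VariantPanel, gm: GenotypeMatrix) -> tuple[VariantPanel, QCReport]:
    """Apply the variant QC rules in fixed order and report per-rule removals.

    1. multi-allelic records; 2. no/ambiguous risk-allele designation;
    3. monomorphic across the provided samples (a single distinct allele
    observed); 4. any missing call.  First matching rule gets the attribution.
    """
    report = QCReport()
    kept: list[VariantRecord] = []
    for r in panel:
        if r.rsid not in gm.rsid_index:
            raise PanelError(f"panel snp {r.rsid} absent from genotype matrix")
        if not r.biallelic or r.rsid in gm.multiallelic:
            report.removed["multiallelic"].append(r.rsid)
            continue
        if r.risk_allele not in (r.ref, r.alt):
            report.removed["no_risk_designation"].append(r.rsid)
            continue
        calls = [c for c in gm.column(r.rsid) if c is not None]
        observed = {a for c in calls for a in c}
        if calls and len(observed) <= 1:
            report.removed["monomorphic"].append(r.rsid)
            continue
        if len(calls) < len(gm.samples):
            report.removed["missing_calls"].append(r.rsid)
            continue
        kept.append(r)
        report.survivors.append(r.rsid)
    return VariantPanel(kept), report


def risk_dosage(call: Call, record: VariantRecord) -> int:
    """Number of risk alleles (0, 1 or 2) in an unphased diploid call."""
    if call is None:
        raise PanelError(f"missing call for {record.rsid} (QC contract broken)")
    for a in call:
        if a not in (record.ref, record.alt):
            raise PanelError(
                f"allele {a!r} not in {{ref={record.ref}, alt={record.alt}}} for {record.rsid}"
            )
    return sum(1 for a in call if a == record.risk_allele)
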