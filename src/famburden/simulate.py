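"""Synthetic three-generation family generator.

The study's raw genotype and methylation data are restricted, so every
pipeline stage is exercised on simulated families with known truth: founder
haplotypes with tunable linkage disequilibrium, Mendelian transmission with
recombination, optional missingness and Mendelian-error injection, and
beta-valued methylation with an optional genotype-coupled or
individual-specific shift.

LD model
--------
Haplotypes are generated left-to-right within each gene block through a
latent-uniform copy chain: with probability ``ld_rho`` the latent uniform of
the previous snp is reused, otherwise a fresh uniform is drawn; the allele
state is ``u < f_j`` for the snp's risk-allele frequency ``f_j``.  Copying
at the latent level (rather than copying the allele state itself) keeps
every snp's marginal frequency exactly at its configured value, and for
adjacent snps with equal frequencies the allele-state correlation is exactly
``ld_rho``.  Chains restart at gene-block boundaries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .panel import (
    DEFAULT_REGIONS,
    GenotypeMatrix,
    VariantPanel,
    VariantRecord,
    default_regions,
    write_regions,
    write_vcf,
)
from .pedigree import Individual, Pedigree, Sex, _compatible


class SimulationError(ValueError):
    pass


#: (id, sex, father, mother, affected) rows mirroring the seven-member,
#: three-generation blood core: an affected grandmother whose child married
#: into a grandparent couple's line, and two third-generation brothers.
#: A member with exactly one named parent gets a hidden, non-emitted founder
#: as the missing parent (a marry-in outside the blood core).
DEFAULT_TEMPLATE: tuple[tuple[str, str, str | None, str | None, bool], ...] = (
    ("GP1", "female", None, None, True),
    ("GP2", "male", None, None, False),
    ("GP3", "female", None, None, False),
    ("P1", "male", "GP2", "GP3", False),
    ("P2", "female", None, "GP1", False),
    ("C1", "male", "P1", "P2", False),
    ("C2", "male", "P1", "P2", False),
)

#: rs429358 and rs7412 are always placed at their GRCh37 coordinates with
#: their real allele coding so epsilon calling runs on synthetic output.
APOE_EPSILON_SNPS = (
    # rsid, pos, ref, alt, risk allele, risk-allele frequency
    ("rs429358", 45_411_941, "T", "C", "C", 0.12),
    ("rs7412", 45_412_079, "C", "T", "T", 0.08),
)

_BASES = ("A", "C", "G", "T")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic family.

    Defaults emulate the seven-member pedigree and its 320-snp six-gene risk
    panel; risk-allele frequencies are kept low (2-15%) so family burden
    totals land in the tens of alleles, as in the motivating family.
    """

    seed: int = 0
    pedigree_template: tuple = DEFAULT_TEMPLATE
    family_id: str = "SYN1"
    snps_per_gene: Mapping[str, int] = field(
        default_factory=lambda: {
            "ABCA7": 101,
            "PICALM": 89,
            "CR1": 84,
            "CLU": 29,
            "BIN1": 8,
            "APOE": 9,
        }
    )
    freq_range: tuple[float, float] = (0.02, 0.15)
    ld_rho: float = 0.8
    recomb_p: float = 0.01
    missing_rate: float = 0.0
    mendelian_errors: int = 0
    # methylation
    probes_per_gene: int = 12
    decoy_probes_per_gene: int = 3
    baseline_beta: Mapping[str, float] | float = 0.5
    meth_noise_sd: float = 0.05  # SD on the logit scale
    coupling_slope: Mapping[str, float] = field(default_factory=dict)
    affected_offset: float = -0.1  # logit shift applied to affected members
    detp_fail_rate: float = 0.02

    def __post_init__(self) -> None:
        for p in (self.ld_rho, self.recomb_p, self.missing_rate, self.detp_fail_rate):
            if not 0.0 <= p <= 1.0:
                raise SimulationError(f"probability {p} outside [0, 1]")
        lo, hi = self.freq_range
        if not (0.0 < lo <= hi < 1.0):
            raise SimulationError("freq_range must satisfy 0 < lo <= hi < 1")
        if self.mendelian_errors < 0:
            raise SimulationError("mendelian_errors must be >= 0")

    def baseline_for(self, gene: str) -> float:
        b = (
            self.baseline_beta.get(gene, 0.5)
            if isinstance(self.baseline_beta, Mapping)
            else float(self.baseline_beta)
        )
        if not 0.0 < b < 1.0:
            raise SimulationError(f"baseline beta for {gene} outside (0, 1)")
        return b


# ---------------------------------------------------------------------------
# Panel construction
# ---------------------------------------------------------------------------


def build_panel(cfg: SimulationConfig, rng: np.random.Generator):
    """Lay synthetic snps inside the real candidate-gene regions.

    Returns (panel, risk-allele frequencies, block start indices).  Snps are
    sorted by genomic coordinate; gene blocks are contiguous.
    """
    gene_order = sorted(
        cfg.snps_per_gene,
        key=lambda g: (
            int(DEFAULT_REGIONS[g][0]) if DEFAULT_REGIONS[g][0].isdigit() else 99,
            DEFAULT_REGIONS[g][1],
        ),
    )
    records: list[VariantRecord] = []
    freqs: list[float] = []
    block_starts: list[int] = []
    counter = 1
    lo, hi = cfg.freq_range
    for gene in gene_order:
        chrom, start, end = DEFAULT_REGIONS[gene]
        n = int(cfg.snps_per_gene[gene])
        if n <= 0:
            continue
        block_starts.append(len(records))
        fixed = list(APOE_EPSILON_SNPS) if gene == "APOE" else []
        n_synth = n - len(fixed)
        if n_synth < 0:
            raise SimulationError(f"APOE needs at least {len(fixed)} snps")
        taken = {pos for _, pos, *_ in fixed}
        positions = []
        step = max((end - start) // (n_synth + 1), 1)
        pos = start
        while len(positions) < n_synth:
            pos += step
            while pos in taken or pos in positions:
                pos += 1
            positions.append(pos)
        rows = []
        for p in positions:
            ref, alt = rng.choice(4, size=2, replace=False)
            ref_b, alt_b = _BASES[ref], _BASES[alt]
            risk = alt_b if rng.random() < 0.5 else ref_b
            rows.append(
                (f"rsS{counter:06d}", p, ref_b, alt_b, risk, float(rng.uniform(lo, hi)))
            )
            counter += 1
        for rsid, p, ref_b, alt_b, risk, f in fixed:
            rows.append((rsid, p, ref_b, alt_b, risk, f))
        rows.sort(key=lambda r: r[1])
        for rsid, p, ref_b, alt_b, risk, f in rows:
            records.append(
                VariantRecord(rsid, chrom, p, ref_b, alt_b, risk, gene, "synthetic")
            )
            freqs.append(f)
    return VariantPanel(records), np.asarray(freqs), np.asarray(block_starts, dtype=int)


# ---------------------------------------------------------------------------
# Haplotypes and meiosis
# ---------------------------------------------------------------------------


def draw_haplotypes(
    freqs: np.ndarray,
    rho: float,
    n_haplotypes: int,
    rng: np.random.Generator,
    block_starts: Sequence[int] = (0,),
) -> np.ndarray:
    """Draw (n_haplotypes, n_snps) risk/non-risk states via the latent copy chain."""
    m = len(freqs)
    fresh = rng.random((n_haplotypes, m))
    copy = rng.random((n_haplotypes, m)) < rho
    copy[:, list(block_starts)] = False
    src = np.where(~copy, np.arange(m)[None, :], -1)
    last_fresh = np.maximum.accumulate(src, axis=1)
    u = np.take_along_axis(fresh, last_fresh, axis=1)
    return (u < freqs[None, :]).astype(np.int8)


def simulate_founder_haplotypes(
    cfg: SimulationConfig, n_founders: int, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, VariantPanel, np.ndarray]:
    """Per-founder haplotype pairs for a panel drawn from ``cfg``.

    Returns (haplotypes of shape (n_founders, 2, n_snps), panel, frequencies).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    panel, freqs, blocks = build_panel(cfg, rng)
    haps = draw_haplotypes(freqs, cfg.ld_rho, 2 * n_founders, rng, blocks)
    return haps.reshape(n_founders, 2, -1), panel, freqs


def meiosis(
    parent_haplotypes: np.ndarray,
    recomb_p: float,
    rng: np.random.Generator,
    block_starts: Sequence[int] = (0,),
) -> np.ndarray:
    """One gamete from a (2, n_snps) pair of parental haplotypes.

    Within each block the active haplotype starts uniformly at random and
    switches at every adjacent interval with probability ``recomb_p``; blocks
    (chromosomal gene regions) assort independently.
    """
    haps = np.asarray(parent_haplotypes)
    if haps.ndim != 2 or haps.shape[0] != 2:
        raise SimulationError("parent_haplotypes must have shape (2, n_snps)")
    m = haps.shape[1]
    starts = sorted(set(int(b) for b in block_starts) | {0})
    bounds = starts + [m]
    active = np.empty(m, dtype=np.int64)
    for s, e in zip(bounds, bounds[1:]):
        first = int(rng.integers(2))
        switches = rng.random(e - s) < recomb_p
        switches[0] = False
        active[s:e] = (first + np.cumsum(switches)) % 2
    return haps[active, np.arange(m)]


# ---------------------------------------------------------------------------
# Family simulation
# ---------------------------------------------------------------------------

_SEX = {"male": Sex.MALE, "female": Sex.FEMALE, "unknown": Sex.UNKNOWN}


@dataclass
class SimulatedFamily:
    pedigree: Pedigree
    genotypes: GenotypeMatrix
    panel: VariantPanel
    regions: pd.DataFrame
    truth: dict


def _nonrisk(record: VariantRecord) -> str:
    return record.alt if record.risk_allele == record.ref else record.ref


def _state_to_call(record: VariantRecord, s1: int, s2: int) -> tuple[str, str]:
    a = record.risk_allele if s1 else _nonrisk(record)
    b = record.risk_allele if s2 else _nonrisk(record)
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def simulate_family(cfg: SimulationConfig) -> SimulatedFamily:
    """Founders drawn from the LD model, non-founders by meiosis; fully seeded.

    The truth record stores all haplotypes, per-individual true per-gene
    dosages (computed from haplotypes before any corruption), configured
    frequencies, and the injected missing calls and Mendelian errors.
    """
    rng = np.random.default_rng(cfg.seed)
    panel, freqs, blocks = build_panel(cfg, rng)
    m = len(panel)
    template = list(cfg.pedigree_template)
    ids = [row[0] for row in template]
    known = set(ids)
    for row in template:
        for parent in (row[2], row[3]):
            if parent is not None and parent not in known:
                raise SimulationError(f"template references absent parent {parent!r}")

    # hidden founder mates for members with exactly one named parent
    sim_parents: dict[str, tuple[str | None, str | None]] = {}
    hidden: list[str] = []
    for iid, _sex, fat, mot, _aff in template:
        if (fat is None) != (mot is None):
            mate = f"_ext_{iid}"
            hidden.append(mate)
            sim_parents[iid] = (fat or mate, mot or mate)
        else:
            sim_parents[iid] = (fat, mot)

    founders = [iid for iid in ids if sim_parents[iid] == (None, None)] + hidden
    founder_haps = draw_haplotypes(freqs, cfg.ld_rho, 2 * len(founders), rng, blocks)
    haplotypes: dict[str, np.ndarray] = {
        iid: founder_haps[2 * k : 2 * k + 2] for k, iid in enumerate(founders)
    }

    remaining = [iid for iid in ids if iid not in haplotypes]
    while remaining:
        progressed = False
        for iid in list(remaining):
            fat, mot = sim_parents[iid]
            if fat in haplotypes and mot in haplotypes:
                paternal = meiosis(haplotypes[fat], cfg.recomb_p, rng, blocks)
                maternal = meiosis(haplotypes[mot], cfg.recomb_p, rng, blocks)
                haplotypes[iid] = np.stack([paternal, maternal])
                remaining.remove(iid)
                progressed = True
        if not progressed:
            raise SimulationError("unresolvable parentage in template")

    individuals = [
        Individual(id=iid, sex=_SEX[sex], father_id=fat, mother_id=mot, affected=aff)
        for iid, sex, fat, mot, aff in template
    ]
    pedigree = Pedigree(family_id=cfg.family_id, individuals=individuals)

    records = panel.records
    gene_of = [r.gene for r in records]
    genes = panel.genes
    true_dosages = {
        iid: {
            g: int(
                sum(
                    int(haplotypes[iid][0, j] + haplotypes[iid][1, j])
                    for j in range(m)
                    if gene_of[j] == g
                )
            )
            for g in genes
        }
        for iid in ids
    }

    calls = np.empty((len(ids), m), dtype=object)
    for i, iid in enumerate(ids):
        h = haplotypes[iid]
        for j, r in enumerate(records):
            calls[i, j] = _state_to_call(r, int(h[0, j]), int(h[1, j]))
    gm = GenotypeMatrix(ids, panel.rsids, calls)

    missing_log: list[tuple[str, str]] = []
    if cfg.missing_rate > 0:
        mask = rng.random((len(ids), m)) < cfg.missing_rate
        for i, iid in enumerate(ids):
            for j in np.flatnonzero(mask[i]):
                gm.calls[i, j] = None
                missing_log.append((iid, panel.rsids[j]))

    error_log: list[tuple[str, str]] = []
    if cfg.mendelian_errors > 0:
        # corrupt leaf children only: corrupting an individual who is also a
        # parent would cascade extra violations into its children's trios
        parents_set = {p for iid in ids for p in sim_parents[iid] if p}
        candidates: list[tuple[str, int, tuple[str, str]]] = []
        for iid in ids:
            if iid in parents_set:
                continue
            fat, mot = pedigree[iid].father_id, pedigree[iid].mother_id
            if fat is None and mot is None:
                continue
            for j, r in enumerate(records):
                child = gm.calls[gm.sample_index[iid], j]
                f = gm.calls[gm.sample_index[fat], j] if fat else None
                mcall = gm.calls[gm.sample_index[mot], j] if mot else None
                if child is None or (f is None and mcall is None):
                    continue
                ref, alt = r.ref, r.alt
                for bad in ((ref, ref), tuple(sorted((ref, alt))), (alt, alt)):
                    if bad != child and not _compatible(bad, f, mcall):
                        candidates.append((iid, j, bad))
                        break
        if len(candidates) < cfg.mendelian_errors:
            raise SimulationError(
                f"only {len(candidates)} injectable Mendelian-error sites available"
            )
        # at most one injected error per (child, snp) site
        picks = rng.choice(len(candidates), size=cfg.mendelian_errors, replace=False)
        for k in sorted(int(p) for p in picks):
            iid, j, bad = candidates[k]
            gm.calls[gm.sample_index[iid], j] = bad
            error_log.append((iid, panel.rsids[j]))

    truth = {
        "seed": cfg.seed,
        "frequencies": {panel.rsids[j]: float(freqs[j]) for j in range(m)},
        "haplotypes": {iid: haplotypes[iid].tolist() for iid in ids},
        "true_gene_dosages": true_dosages,
        "true_totals": {iid: int(sum(d.values())) for iid, d in true_dosages.items()},
        "injected_missing": [list(t) for t in missing_log],
        "injected_mendelian_errors": [list(t) for t in error_log],
    }
    return SimulatedFamily(pedigree, gm, panel, default_regions(), truth)


# ---------------------------------------------------------------------------
# Methylation simulation
# ---------------------------------------------------------------------------


def simulate_methylation(cfg: SimulationConfig, bt) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Beta matrix, probe manifest and detection-p matrix for scored individuals.

    For gene g and individual i each probe's beta is
    ``expit(logit(baseline_g) + slope_g * count_ig + offset_i + noise)``;
    the affected-member offset emulates an individual-specific
    hypomethylation shift.  Decoy probes outside every gene window carry
    baseline signal only.  Uses an rng stream derived from (seed, 1) so
    genotype output is unchanged by toggling methylation simulation.
    """
    rng = np.random.default_rng([cfg.seed, 1])
    affected = {
        row[0] for row in cfg.pedigree_template if len(row) > 4 and row[4]
    }
    individuals = list(bt.individuals)
    offsets = {i: (cfg.affected_offset if i in affected else 0.0) for i in individuals}

    probe_rows = []
    counter = 1
    for gene, (chrom, start, end) in DEFAULT_REGIONS.items():
        if gene not in bt.genes:
            continue
        step = max((end - start) // (cfg.probes_per_gene + 1), 1)
        for k in range(cfg.probes_per_gene):
            probe_rows.append((f"cgS{counter:06d}", chrom, start + (k + 1) * step, gene))
            counter += 1
        for k in range(cfg.decoy_probes_per_gene):
            # well outside the gene window (beyond the 10 kb flank)
            probe_rows.append((f"cgS{counter:06d}", chrom, start - 15_000 - k * 977, None))
            counter += 1

    betas = np.empty((len(probe_rows), len(individuals)))
    for pi, (_pid, _chrom, _pos, gene) in enumerate(probe_rows):
        base = cfg.baseline_for(gene) if gene is not None else 0.5
        slope = cfg.coupling_slope.get(gene, 0.0) if gene is not None else 0.0
        for si, iid in enumerate(individuals):
            count = bt.gene_count(iid, gene) if gene is not None else 0
            z = logit(base) + slope * count + offsets[iid]
            if cfg.meth_noise_sd > 0:
                z += rng.normal(0.0, cfg.meth_noise_sd)
            betas[pi, si] = expit(z)

    probe_ids = [r[0] for r in probe_rows]
    beta_df = pd.DataFrame(betas, index=probe_ids, columns=individuals)
    beta_df.index.name = "probe_id"
    manifest = pd.DataFrame(
        {
            "chrom": [r[1] for r in probe_rows],
            "pos": [r[2] for r in probe_rows],
            "snp_overlap": False,
            "cross_reactive": False,
            "sex_chromosome": False,
        },
        index=pd.Index(probe_ids, name="probe_id"),
    )

    detp = pd.DataFrame(
        rng.uniform(1e-5, 5e-3, size=betas.shape), index=beta_df.index, columns=individuals
    )
    fail = rng.random(len(probe_rows)) < cfg.detp_fail_rate
    for pi in np.flatnonzero(fail):
        si = int(rng.integers(len(individuals)))
        detp.iloc[pi, si] = float(rng.uniform(0.02, 0.2))
    detp.index.name = "probe_id"
    return beta_df, manifest, detp


# ---------------------------------------------------------------------------
# Dataset emission
# ---------------------------------------------------------------------------


def write_dataset(cfg: SimulationConfig, outdir: str | Path) -> dict[str, Path]:
    """Simulate a family + methylation and emit every pipeline input file.

    Files: pedigree.ped, genotypes.vcf, panel.tsv, regions.tsv, beta.tsv,
    manifest.tsv, detection_p.tsv, truth.json.  Byte-identical across runs
    for a fixed config.
    """
    from .burden import compute_gbs

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fam = simulate_family(cfg)
    # methylation is coupled to the uncorrupted burden truth
    clean = pd.DataFrame(fam.truth["true_gene_dosages"]).T.loc[fam.genotypes.samples]
    from .burden import BurdenTable

    bt = BurdenTable(clean[fam.panel.genes], fam.panel.per_gene_counts())
    beta, manifest, detp = simulate_methylation(cfg, bt)

    paths = {
        "pedigree": outdir / "pedigree.ped",
        "vcf": outdir / "genotypes.vcf",
        "panel": outdir / "panel.tsv",
        "regions": outdir / "regions.tsv",
        "beta": outdir / "beta.tsv",
        "manifest": outdir / "manifest.tsv",
        "detection_p": outdir / "detection_p.tsv",
        "truth": outdir / "truth.json",
    }
    fam.pedigree.write_ped(paths["pedigree"])
    write_vcf(fam.genotypes, fam.panel, paths["vcf"])
    fam.panel.write_tsv(paths["panel"])
    write_regions(fam.regions, paths["regions"])
    beta.to_csv(paths["beta"], sep="\t", float_format="%.6f")
    manifest.to_csv(paths["manifest"], sep="\t")
    detp.to_csv(paths["detection_p"], sep="\t", float_format="%.6g")
    paths["truth"].write_text(json.dumps(fam.truth, indent=1, sort_keys=True) + "\n")
    return paths
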