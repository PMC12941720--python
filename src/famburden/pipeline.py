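"""End-to-end pipeline: load -> blood relatives -> QC -> GBS -> epsilon ->
methylation -> statistics, bundled into a single JSON-serializable report."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any

import yaml

from . import __version__
from . import apoe as apoe_mod
from . import burden as burden_mod
from . import methylation as meth_mod
from . import panel as panel_mod
from . import pedigree as ped_mod

log = logging.getLogger("famburden")


class PipelineError(RuntimeError):
    """Stage failure with the stage name attached."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage
        self.cause = cause


_PATH_FIELDS = (
    "pedigree",
    "vcf",
    "panel",
    "regions",
    "direct_genotypes",
    "beta",
    "manifest",
    "detection_p",
    "snp_mask",
    "cross_reactive_mask",
)


@dataclass
class RunConfig:
    """Inputs and parameters of one pipeline run.

    Defaults reproduce the analysis parameters: ±50 kb variant flanks,
    ±10 kb probe flanks, detection-p threshold 0.01, 1-decimal burden
    display and 3-decimal correlations.
    """

    pedigree: str
    vcf: str
    panel: str
    regions: str
    direct_genotypes: str | None = None  # side TSV: sample_id, rsid, gt
    beta: str | None = None
    manifest: str | None = None
    detection_p: str | None = None
    snp_mask: str | None = None
    cross_reactive_mask: str | None = None
    probands: list[str] | None = None  # default: deepest generation
    flank_bp_variants: int = 50_000
    flank_bp_probes: int = 10_000
    detp_threshold: float = 0.01
    burden_decimals: int = 1
    correlation_decimals: int = 3
    seed: int = 0
    verbosity: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        raw = yaml.safe_load(path.read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in _PATH_FIELDS:
            if raw.get(key):
                p = Path(raw[key])
                if not p.is_absolute():
                    raw[key] = str((path.parent / p).resolve())
        return cls(**raw)

    def sha256(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclass
class FamilyReport:
    """Full-precision results; display rounding derives from stored values."""

    data: dict[str, Any]

    def to_json(self) -> str:
        return json.dumps(self.data, indent=2, sort_keys=True, allow_nan=False)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")

    def __getitem__(self, key: str) -> Any:
        return self.data[key]

    def __contains__(self, key: str) -> bool:
        return key in self.data


def _summary_dict(s: burden_mod.GroupSummary, decimals: int) -> dict[str, Any]:
    return {
        "label": s.label,
        "n": s.n,
        "mean": s.mean,
        "sd": s.sd,
        "min": s.min,
        "max": s.max,
        "display": s.display(decimals),
    }


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001 - re-raised with stage tag
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(cfg: RunConfig) -> FamilyReport:
    """Execute every stage and bundle the statistics the family report prints.

    Degenerate inputs degrade gracefully: an empty post-QC panel yields a
    report without a burden block (with a warning); missing epsilon-defining
    genotypes drop only the carrier comparison.
    """
    checksums = _stage("read_inputs")(
        lambda: {
            key: _file_sha256(getattr(cfg, key))
            for key in _PATH_FIELDS
            if getattr(cfg, key)
        }
    )()
    report: dict[str, Any] = {
        "provenance": {
            "tool": "famburden",
            "version": __version__,
            "config_sha256": cfg.sha256(),
            "input_sha256": checksums,
        }
    }
    dec = cfg.burden_decimals

    ped = _stage("load_pedigree")(ped_mod.load_pedigree)(cfg.pedigree)
    log.info("pedigree: %d members", len(ped))
    gens_all = ped_mod.assign_generations(ped)
    probands = cfg.probands or [
        i for i in ped.ids if gens_all[i] == max(gens_all.values())
    ]
    blood = _stage("blood_relatives")(ped_mod.blood_relatives)(ped, probands)
    gens = ped_mod.assign_generations(blood)
    log.info("blood relatives of %s: %d members", probands, len(blood))
    report["pedigree"] = {
        "family_id": ped.family_id,
        "n_members": len(ped),
        "probands": probands,
        "n_blood_relatives": len(blood),
        "generations": gens,
        "affected": [i.id for i in blood if i.affected],
    }

    regions = _stage("load_regions")(panel_mod.load_regions)(cfg.regions)
    panel = _stage("load_panel")(panel_mod.load_panel)(cfg.panel)
    gm = _stage("load_genotypes")(panel_mod.load_genotypes)(
        cfg.vcf, [i for i in blood.ids]
    )
    if cfg.direct_genotypes:
        gm = _stage("merge_direct_genotypes")(panel_mod.merge_direct_genotypes)(
            gm, cfg.direct_genotypes
        )
    in_region = _stage("extract_region_variants")(panel_mod.extract_region_variants)(
        panel, regions, cfg.flank_bp_variants
    )
    scored_panel, qc = _stage("apply_qc_filters")(panel_mod.apply_qc_filters)(
        in_region, gm
    )
    log.info(
        "panel: %d loaded, %d in region, %d after QC", len(panel), len(in_region), len(scored_panel)
    )
    report["qc"] = {
        "n_panel": len(panel),
        "n_in_region": len(in_region),
        "removed": qc.counts,
        "n_scored": len(scored_panel),
    }

    violations = _stage("check_mendelian")(ped_mod.check_mendelian)(
        blood, gm
    )
    report["mendelian_violations"] = [
        {"individual_id": v.individual_id, "rsid": v.rsid, "child_gt": v.child_gt}
        for v in violations
    ]
    if violations:
        log.warning("%d Mendelian violations flagged", len(violations))

    # -- epsilon diplotypes -------------------------------------------------
    carrier_flags: dict[str, bool] | None = None
    if "rs429358" in gm.rsid_index and "rs7412" in gm.rsid_index:
        calls = {}
        for s in gm.samples:
            g1, g2 = gm.call(s, "rs429358"), gm.call(s, "rs7412")
            if g1 is None or g2 is None:
                continue
            calls[s] = (g1, g2)
        rows = _stage("call_apoe")(apoe_mod.apoe_table)(calls)
        report["apoe"] = {
            r["sample_id"]: {
                "diplotype": r["diplotype"],
                "e4_carrier": r["e4_carrier"],
                "ambiguous": r["ambiguous"],
            }
            for r in rows
        }
        carrier_flags = {r["sample_id"]: bool(r["e4_carrier"]) for r in rows}
    else:
        log.warning("rs429358/rs7412 unavailable: epsilon block absent")

    # -- burden statistics --------------------------------------------------
    bt = None
    if len(scored_panel) == 0:
        log.warning("no variants survived QC: burden block absent")
    else:
        bt = _stage("compute_gbs")(burden_mod.compute_gbs)(gm, scored_panel)
        gene_means = bt.gene_means()
        total_mean = float(bt.totals.mean())
        stats: dict[str, Any] = {
            "per_individual_total": {i: bt.total(i) for i in bt.individuals},
            "per_individual_gene_counts": {
                i: {g: bt.gene_count(i, g) for g in bt.genes} for i in bt.individuals
            },
            "snps_per_gene": bt.snps_per_gene,
            "overall": _summary_dict(
                burden_mod.summarize(list(bt.totals), "family"), dec
            ),
            "per_generation": [
                _summary_dict(s, dec)
                for s in burden_mod.generation_summary(bt, blood)
            ],
            "gene_means": gene_means,
            "contribution_percent": burden_mod.contribution_percentages(
                gene_means, total_mean
            ),
        }
        sibs = blood.full_sib_pairs()
        discord = []
        for a, b in sibs:
            delta, rel = burden_mod.relative_discordance(bt.total(a), bt.total(b))
            gd = burden_mod.gene_deltas(bt, a, b)
            discord.append(
                {
                    "pair": [a, b],
                    "delta": delta,
                    "relative_percent": rel,
                    "gene_deltas": {g: int(gd.loc[g, "signed_delta"]) for g in bt.genes},
                }
            )
        stats["sibling_discordance"] = discord
        if carrier_flags is not None:
            try:
                cc = burden_mod.carrier_comparison(bt, carrier_flags)
                stats["carrier_comparison"] = {
                    "carriers": _summary_dict(cc.carriers, dec),
                    "non_carriers": _summary_dict(cc.non_carriers, dec),
                    "mean_difference": cc.mean_difference,
                }
            except burden_mod.BurdenError as exc:
                log.warning("carrier comparison skipped: %s", exc)
        values = [bt.total(i) for i in bt.individuals]
        groups = [gens[i] for i in bt.individuals]
        if len(set(groups)) >= 2:
            icc = burden_mod.icc_oneway(values, groups)
            stats["icc"] = {"icc": icc.icc, "msb": icc.msb, "msw": icc.msw, "k0": icc.k0}
            trend = burden_mod.generation_trend(values, groups)
            stats["generation_trend"] = {
                "slope": trend.slope,
                "intercept": trend.intercept,
                "r": trend.r,
            }
        report["burden"] = stats

    # -- methylation --------------------------------------------------------
    if cfg.beta and cfg.manifest:
        betas = _stage("load_beta")(meth_mod.load_beta_matrix)(cfg.beta)
        manifest = _stage("load_manifest")(meth_mod.load_manifest)(cfg.manifest)
        if cfg.snp_mask or cfg.cross_reactive_mask:
            snp_list = (
                Path(cfg.snp_mask).read_text().split() if cfg.snp_mask else []
            )
            xr_list = (
                Path(cfg.cross_reactive_mask).read_text().split()
                if cfg.cross_reactive_mask
                else []
            )
            manifest = meth_mod.apply_mask_lists(manifest, snp_list, xr_list)
        detp = (
            meth_mod.load_detection_p(cfg.detection_p) if cfg.detection_p else None
        )
        kept, filt = _stage("filter_probes")(meth_mod.filter_probes)(
            manifest, betas, detp, cfg.detp_threshold
        )
        log.info("probes: %d kept of %d", len(kept), len(betas))
        betas_kept = betas.loc[kept]
        gms = _stage("gene_methylation_summary")(meth_mod.gene_methylation_summary)(
            betas_kept, manifest, regions, cfg.flank_bp_probes
        )
        meth_block: dict[str, Any] = {
            "n_probes_input": int(len(betas)),
            "n_probes_kept": len(kept),
            "filter_counts": filt.counts,
            "gene_mean_beta": {
                g: {i: float(gms.means.loc[i, g]) for i in gms.means.index}
                for g in gms.genes
            },
            "probes_per_gene": gms.probe_counts,
        }
        if bt is not None and len(gms.genes) > 0:
            corr = _stage("genotype_methylation_correlation")(
                meth_mod.genotype_methylation_correlation
            )(bt, gms)
            meth_block["genotype_methylation_r"] = {
                g: (None if not corr.loc[g, "defined"] else float(corr.loc[g, "r"]))
                for g in corr.index
            }
        if len(betas_kept.columns) >= 2 and len(betas_kept) > 0:
            merges = _stage("hier_cluster")(meth_mod.hier_cluster)(
                betas_kept.to_numpy().T
            )
            labels = list(betas_kept.columns)
            meth_block["cluster_merges"] = [
                {
                    "cluster_a": [labels[i] for i in m.left],
                    "cluster_b": [labels[i] for i in m.right],
                    "height": m.height,
                }
                for m in merges
            ]
        report["methylation"] = meth_block

    return FamilyReport(report)
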