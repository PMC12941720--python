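"""CpG beta values, probe filtering, gene-level summaries and clustering.

Beta is the methylation fraction at a probe, M / (M + U), bounded in [0, 1].
The pipeline consumes a probe x sample beta matrix plus a probe manifest
(probe id, chromosome, 1-based CpG position, quality flags); raw IDAT
processing and normalization are upstream and out of scope.  Gene-level
summaries average beta over probes inside a candidate-gene region ± 10 kb.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .panel import PanelError, _flanked, norm_chrom


class MethylationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Beta computation and IO
# ---------------------------------------------------------------------------


def compute_beta(meth_intensity, unmeth_intensity, offset: float = 0.0):
    """beta = M / (M + U + offset); the default offset is 0 (formula as stated).

    Accepts scalars or arrays.  With offset 0, a probe where both intensities
    are zero is undefined and raises.
    """
    m = np.asarray(meth_intensity, dtype=float)
    u = np.asarray(unmeth_intensity, dtype=float)
    if (m < 0).any() or (u < 0).any():
        raise MethylationError("intensities must be non-negative")
    denom = m + u + offset
    if (denom == 0).any():
        raise MethylationError("both intensities zero (beta undefined)")
    beta = m / denom
    return float(beta) if beta.ndim == 0 else beta


MANIFEST_FLAGS = ("snp_overlap", "cross_reactive", "sex_chromosome")


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Probe manifest TSV: probe_id, chrom, pos [+ optional boolean flag columns]."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = {"probe_id", "chrom", "pos"} - set(df.columns)
    if missing:
        raise MethylationError(f"manifest missing columns: {sorted(missing)}")
    if df["probe_id"].duplicated().any():
        raise MethylationError("duplicate probe ids in manifest")
    df = df.copy()
    df["chrom"] = df["chrom"].map(norm_chrom)
    df["pos"] = df["pos"].astype(int)
    for flag in MANIFEST_FLAGS:
        if flag in df.columns:
            df[flag] = df[flag].astype(bool)
        else:
            df[flag] = False
    return df.set_index("probe_id")


def load_beta_matrix(path: str | Path) -> pd.DataFrame:
    """Probe x sample beta TSV (first column = probe id)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    vals = df.to_numpy(dtype=float)
    if ((vals < 0) | (vals > 1)).any():
        raise MethylationError("beta values must lie in [0, 1]")
    return df


def load_detection_p(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def apply_mask_lists(
    manifest: pd.DataFrame,
    snp_probes: Iterable[str] = (),
    cross_reactive_probes: Iterable[str] = (),
) -> pd.DataFrame:
    """Set snp_overlap / cross_reactive flags from user-supplied probe lists."""
    out = manifest.copy()
    out.loc[out.index.intersection(list(snp_probes)), "snp_overlap"] = True
    out.loc[out.index.intersection(list(cross_reactive_probes)), "cross_reactive"] = True
    return out


# ---------------------------------------------------------------------------
# Probe filtering
# ---------------------------------------------------------------------------

FILTER_RULES = ("detection_p", "snp_overlap", "cross_reactive", "sex_chromosome")


@dataclass
class ProbeFilterReport:
    removed: dict[str, list[str]] = field(
        default_factory=lambda: {rule: [] for rule in FILTER_RULES}
    )
    kept: list[str] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {rule: len(v) for rule, v in self.removed.items()}


def filter_probes(
    manifest: pd.DataFrame,
    betas: pd.DataFrame,
    detp: pd.DataFrame | None = None,
    detp_threshold: float = 0.01,
) -> tuple[list[str], ProbeFilterReport]:
    """Drop unreliable probes; attribute each drop to the first failing rule.

    Rules, in order: detection p-value > threshold in any sample (strict
    "any sample" reading); SNP-overlap flag; cross-reactive flag;
    sex-chromosome flag.  The kept set is independent of probe order.
    """
    missing = betas.index.difference(manifest.index)
    if len(missing):
        raise MethylationError(f"probes absent from manifest: {list(missing[:5])}...")
    report = ProbeFilterReport()
    if detp is not None:
        detp = detp.reindex(index=betas.index, columns=betas.columns)
        if detp.isna().any().any():
            raise MethylationError("detection-p matrix does not cover beta matrix")
    for probe in betas.index:
        row = manifest.loc[probe]
        if detp is not None and (detp.loc[probe] > detp_threshold).any():
            report.removed["detection_p"].append(probe)
        elif bool(row["snp_overlap"]):
            report.removed["snp_overlap"].append(probe)
        elif bool(row["cross_reactive"]):
            report.removed["cross_reactive"].append(probe)
        elif bool(row["sex_chromosome"]) or row["chrom"] in ("X", "Y"):
            report.removed["sex_chromosome"].append(probe)
        else:
            report.kept.append(probe)
    return report.kept, report


# ---------------------------------------------------------------------------
# Gene-level summaries
# ---------------------------------------------------------------------------


@dataclass
class GeneMethylationSummary:
    """Per (individual, gene) mean beta plus the probe count used per gene.

    Genes without any in-window probe are absent (not reported as 0).
    """

    means: pd.DataFrame  # individuals x genes
    probe_counts: dict[str, int]

    @property
    def genes(self) -> list[str]:
        return list(self.means.columns)

    def to_tsv(self, path: str | Path) -> None:
        self.means.to_csv(path, sep="\t", index_label="individual_id")


def gene_methylation_summary(
    betas: pd.DataFrame,
    manifest: pd.DataFrame,
    regions: pd.DataFrame,
    flank_bp: int = 10_000,
) -> GeneMethylationSummary:
    """Mean beta per individual over probes within each gene region ± flank.

    Boundaries inclusive; flanked regions must not overlap on a chromosome
    (probe assignment would be ambiguous).
    """
    windows = _flanked(regions, flank_bp)
    manifest = manifest.loc[betas.index]
    means: dict[str, pd.Series] = {}
    probe_counts: dict[str, int] = {}
    for chrom, start, end, gene in windows:
        in_window = manifest[
            (manifest["chrom"] == chrom)
            & (manifest["pos"] >= start)
            & (manifest["pos"] <= end)
        ].index
        if len(in_window) == 0:
            continue
        means[gene] = betas.loc[in_window].mean(axis=0)
        probe_counts[gene] = int(len(in_window))
    order = [g for g in regions["gene"] if g in means]
    df = pd.DataFrame({g: means[g] for g in order})
    df.index.name = "individual_id"
    return GeneMethylationSummary(means=df, probe_counts=probe_counts)


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation; requires length >= 3 and nonzero variances."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size != ya.size:
        raise MethylationError("vectors must have equal length")
    if xa.size < 3:
        raise MethylationError("need at least 3 observations")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise MethylationError("zero variance in an input vector")
    return float(sps.pearsonr(xa, ya).statistic)


def genotype_methylation_correlation(
    bt, gms: GeneMethylationSummary
) -> pd.DataFrame:
    """Per-gene Pearson r between risk-allele counts and mean beta.

    Rows: genes present in both the burden table and the methylation summary.
    A gene where either vector is constant is flagged ``defined=False`` with
    r = NaN rather than dropped.
    """
    shared = [i for i in bt.individuals if i in gms.means.index]
    if len(shared) < 3:
        raise MethylationError("need >= 3 shared individuals")
    rows = []
    for gene in gms.genes:
        if gene not in bt.genes:
            continue
        counts = np.asarray([bt.gene_count(i, gene) for i in shared], dtype=float)
        meth = gms.means.loc[shared, gene].to_numpy(dtype=float)
        if np.ptp(counts) == 0 or np.ptp(meth) == 0:
            rows.append({"gene": gene, "r": np.nan, "defined": False})
        else:
            rows.append({"gene": gene, "r": pearson(counts, meth), "defined": True})
    return pd.DataFrame(rows).set_index("gene")


# ---------------------------------------------------------------------------
# Hierarchical clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Merge:
    left: tuple[int, ...]  # member indices of the first cluster (sorted)
    right: tuple[int, ...]
    height: float


def hier_cluster(profiles) -> list[Merge]:
    """Agglomerative clustering, complete linkage on Euclidean distances.

    Naive O(n^3) agglomerator over sample rows.  Ties are broken
    deterministically by the lexicographically smallest cluster pair (clusters
    ordered by their sorted member tuples), so the merge tree is a pure
    function of the input.  Complete linkage guarantees non-decreasing merge
    heights.
    """
    X = np.asarray(profiles, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise MethylationError("need a 2-D matrix with >= 2 samples")
    if np.isnan(X).any():
        raise MethylationError("NaN features not allowed")
    n = X.shape[0]
    point_d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(axis=2))
    clusters: list[tuple[int, ...]] = [(i,) for i in range(n)]
    merges: list[Merge] = []
    while len(clusters) > 1:
        best: tuple[float, tuple[int, ...], tuple[int, ...]] | None = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = sorted((clusters[i], clusters[j]))
                d = float(point_d[np.ix_(a, b)].max())
                if best is None or d < best[0] or (d == best[0] and (a, b) < best[1:]):
                    best = (d, a, b)
        d, a, b = best  # type: ignore[misc]
        merges.append(Merge(left=a, right=b, height=d))
        clusters = [c for c in clusters if c not in (a, b)]
        clusters.append(tuple(sorted(a + b)))
    return merges


def merges_to_tsv(merges: Sequence[Merge], labels: Sequence[str], path: str | Path) -> None:
    lines = ["cluster_a\tcluster_b\theight"]
    for m in merges:
        la = ",".join(labels[i] for i in m.left)
        lb = ",".join(labels[i] for i in m.right)
        lines.append(f"{la}\t{lb}\t{m.height:.6g}")
    Path(path).write_text("\n".join(lines) + "\n")
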