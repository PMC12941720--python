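"""Region tables, VCF ingestion, region extraction with flanks, QC filters,
and risk-allele dosage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famburden.panel import (
    GenotypeMatrix,
    PanelError,
    VariantPanel,
    VariantRecord,
    apply_qc_filters,
    default_regions,
    extract_region_variants,
    load_genotypes,
    load_panel,
    load_regions,
    merge_direct_genotypes,
    region_length,
    risk_dosage,
    write_vcf,
)


@pytest.fixture(scope="module")
def regions(tmp_path_factory):
    p = tmp_path_factory.mktemp("regions") / "regions.tsv"
    default_regions().to_csv(p, sep="\t", index=False)
    return load_regions(p)


class TestRegions:
    def test_candidate_gene_lengths(self, regions):
        assert region_length(regions, "APOE") == 3_640
        assert region_length(regions, "CR1") == 173_150
        assert len(regions) == 6

    def test_empty_file(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("gene\tchrom\tstart\tend\n")
        assert len(load_regions(p)) == 0

    def test_start_after_end_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tchrom\tstart\tend\nX\t1\t200\t100\n")
        with pytest.raises(PanelError, match="start > end"):
            load_regions(p)

    def test_duplicate_gene_rejected(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("gene\tchrom\tstart\tend\nX\t1\t1\t2\nX\t2\t1\t2\n")
        with pytest.raises(PanelError, match="duplicate"):
            load_regions(p)

    def test_chr_prefix_normalized(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text("gene\tchrom\tstart\tend\nX\tchr19\t10\t20\n")
        assert load_regions(p)["chrom"].iloc[0] == "19"


def _record(rsid="rs1", chrom="1", pos=1500, ref="A", alt="G", risk="G", gene="X"):
    return VariantRecord(rsid, chrom, pos, ref, alt, risk, gene)


class TestExtractRegionVariants:
    @pytest.mark.parametrize(
        "pos,flank,kept",
        [(950, 50, True), (949, 50, False), (1000, 0, True), (2000, 0, True),
         (2001, 0, False), (2050, 50, True), (2051, 50, False)],
    )
    def test_boundaries_inclusive(self, pos, flank, kept):
        regions = pd.DataFrame([{"gene": "X", "chrom": "1", "start": 1000, "end": 2000}])
        panel = VariantPanel([_record(pos=pos)])
        out = extract_region_variants(panel, regions, flank)
        assert (len(out) == 1) == kept

    def test_matches_per_record_interval_oracle(self, regions, rng):
        records = []
        chroms = ["1", "2", "8", "11", "19", "7"]
        for k in range(100):
            records.append(
                _record(
                    rsid=f"rs{k}",
                    chrom=chroms[rng.integers(len(chroms))],
                    pos=int(rng.integers(1, 250_000_000)),
                    gene="?",
                )
            )
        # spray some guaranteed in-region positions too
        for k, row in enumerate(regions.itertuples()):
            records.append(
                _record(rsid=f"in{k}", chrom=row.chrom, pos=int((row.start + row.end) // 2), gene="?")
            )
        panel = VariantPanel(records)
        out = extract_region_variants(panel, regions, 50_000)
        expected = set()
        for r in records:
            for row in regions.itertuples():
                if r.chrom == row.chrom and row.start - 50_000 <= r.pos <= row.end + 50_000:
                    expected.add(r.rsid)
        assert set(out.rsids) == expected
        # gene labels reassigned to the matching region
        for r in out:
            row = regions.loc[regions["gene"] == r.gene].iloc[0]
            assert row.start - 50_000 <= r.pos <= row.end + 50_000

    @given(f1=st.integers(0, 30_000), f2=st.integers(0, 30_000))
    @settings(max_examples=20, deadline=None)
    def test_flank_monotone_subset(self, regions, f1, f2):
        lo, hi = sorted((f1, f2))
        rng = np.random.default_rng(7)
        records = [
            _record(rsid=f"rs{k}", chrom="19", pos=int(rng.integers(45_300_000, 45_500_000)), gene="?")
            for k in range(40)
        ]
        panel = VariantPanel(records)
        small = set(extract_region_variants(panel, regions, lo).rsids)
        big = set(extract_region_variants(panel, regions, hi).rsids)
        assert small <= big

    def test_overlapping_flanked_regions_rejected(self):
        regions = pd.DataFrame(
            [
                {"gene": "A", "chrom": "1", "start": 1000, "end": 2000},
                {"gene": "B", "chrom": "1", "start": 2500, "end": 3000},
            ]
        )
        with pytest.raises(PanelError, match="overlap"):
            extract_region_variants(VariantPanel([]), regions, 300)

    def test_negative_flank_rejected(self, regions):
        with pytest.raises(PanelError):
            extract_region_variants(VariantPanel([]), regions, -1)


def _matrix(samples, calls_by_rsid, multiallelic=()):
    rsids = list(calls_by_rsid)
    calls = np.empty((len(samples), len(rsids)), dtype=object)
    for j, r in enumerate(rsids):
        for i, c in enumerate(calls_by_rsid[r]):
            calls[i, j] = tuple(sorted(c)) if c else None
    return GenotypeMatrix(samples, rsids, calls, multiallelic)


class TestQCFilters:
    def test_planted_defects_counted_per_rule(self, rng):
        """50-snp panel with 3 multi-allelic, 2 monomorphic and 1 missing-bearing
        snp planted -> 44 survive with report {3, 0, 2, 1}."""
        samples = [f"s{i}" for i in range(7)]
        records, calls = [], {}
        multi = []
        for k in range(50):
            rsid = f"rs{k}"
            if k < 3:  # multi-allelic
                records.append(VariantRecord(rsid, "1", 100 + k, "A", "G,T", "G", "X"))
                multi.append(rsid)
                calls[rsid] = [("A", "G")] * 7
            elif k < 5:  # monomorphic
                records.append(_record(rsid=rsid, pos=100 + k))
                calls[rsid] = [("A", "A")] * 7
            elif k == 5:  # one missing call
                records.append(_record(rsid=rsid, pos=100 + k))
                calls[rsid] = [("A", "G")] * 6 + [None]
            else:
                records.append(_record(rsid=rsid, pos=100 + k))
                het = [("A", "G")] * 4 + [("A", "A")] * 3
                rng.shuffle(het)
                calls[rsid] = het
        panel = VariantPanel(records)
        gm = _matrix(samples, calls, multi)
        survivors, report = apply_qc_filters(panel, gm)
        assert len(survivors) == 44
        assert report.counts == {
            "multiallelic": 3,
            "no_risk_designation": 0,
            "monomorphic": 2,
            "missing_calls": 1,
        }
        # independent recount of the planted defects
        assert set(report.removed["multiallelic"]) == {"rs0", "rs1", "rs2"}
        assert set(report.removed["monomorphic"]) == {"rs3", "rs4"}
        assert report.removed["missing_calls"] == ["rs5"]

    def test_bad_risk_designation_dropped(self):
        panel = VariantPanel([_record(risk="T")])  # T not in {A, G}
        gm = _matrix(["a", "b"], {"rs1": [("A", "G"), ("A", "A")]})
        survivors, report = apply_qc_filters(panel, gm)
        assert len(survivors) == 0
        assert report.counts["no_risk_designation"] == 1

    def test_idempotent_and_monotone(self, sim_family):
        survivors, rep = apply_qc_filters(sim_family.panel, sim_family.genotypes)
        assert len(survivors) <= len(sim_family.panel)
        again, rep2 = apply_qc_filters(survivors, sim_family.genotypes)
        assert again.rsids == survivors.rsids
        assert sum(rep2.counts.values()) == 0


class TestRiskDosage:
    @pytest.mark.parametrize(
        "call,risk,expected",
        [
            (("G", "G"), "G", 2),
            (("A", "A"), "G", 0),
            (("A", "G"), "G", 1),
            (("A", "G"), "A", 1),  # risk = ref: guards against alt-only counting
            (("A", "A"), "A", 2),
        ],
    )
    def test_counts_risk_alleles(self, call, risk, expected):
        rec = _record(risk=risk)
        assert risk_dosage(call, rec) == expected
        # complement identity: risk + non-risk alleles = 2
        assert risk_dosage(call, rec) + sum(1 for a in call if a != risk) == 2

    def test_missing_call_raises(self):
        with pytest.raises(PanelError, match="missing"):
            risk_dosage(None, _record())

    def test_foreign_allele_raises(self):
        with pytest.raises(PanelError):
            risk_dosage(("A", "T"), _record())


class TestVcfIO:
    def test_round_trip_synthetic_family(self, sim_family, tmp_path):
        path = tmp_path / "fam.vcf"
        write_vcf(sim_family.genotypes, sim_family.panel, path)
        back = load_genotypes(path)
        assert sorted(back.rsids) == sorted(sim_family.genotypes.rsids)
        for s in sim_family.genotypes.samples:
            for r in sim_family.genotypes.rsids:
                assert back.call(s, r) == sim_family.genotypes.call(s, r)

    def test_missing_and_het_decoding(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/1\t./.\n"
        )
        gm = load_genotypes(vcf)
        assert gm.call("s1", "rs1") == ("A", "G")
        assert gm.call("s2", "rs1") is None

    def test_multiallelic_flagged(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\trs1\tA\tG,T\t.\t.\t.\tGT\t0/1\n"
        )
        assert "rs1" in load_genotypes(vcf).multiallelic

    def test_absent_sample_rejected(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "1\t100\trs1\tA\tG\t.\t.\t.\tGT\t0/0\n"
        )
        with pytest.raises(PanelError, match="absent"):
            load_genotypes(vcf, ["ghost"])


class TestDirectGenotypeMerge:
    def _base(self):
        return _matrix(["s1", "s2"], {"rs1": [("A", "G"), ("A", "A")]})

    def test_adds_new_snp(self, tmp_path):
        tsv = tmp_path / "direct.tsv"
        tsv.write_text(
            "sample_id\trsid\tgt\ns1\trs429358\tC/T\ns2\trs429358\tT/T\n"
        )
        out = merge_direct_genotypes(self._base(), tsv)
        assert out.call("s1", "rs429358") == ("C", "T")
        assert out.call("s2", "rs429358") == ("T", "T")

    def test_conflicting_call_raises(self, tmp_path):
        tsv = tmp_path / "direct.tsv"
        tsv.write_text("sample_id\trsid\tgt\ns1\trs1\tG/G\n")
        with pytest.raises(PanelError, match="disagrees"):
            merge_direct_genotypes(self._base(), tsv)

    def test_agreeing_call_passes(self, tmp_path):
        tsv = tmp_path / "direct.tsv"
        tsv.write_text("sample_id\trsid\tgt\ns1\trs1\tA/G\n")
        out = merge_direct_genotypes(self._base(), tsv)
        assert out.call("s1", "rs1") == ("A", "G")


def test_panel_tsv_round_trip(sim_family, tmp_path):
    p = tmp_path / "panel.tsv"
    sim_family.panel.write_tsv(p)
    back = load_panel(p)
    assert back.rsids == sim_family.panel.rsids
    assert back.per_gene_counts() == sim_family.panel.per_gene_counts()
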