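"""Bundled worked-example dataset: the seven-member three-generation family.

These are the published per-individual summary values for the blood core of
the motivating family (three grandparents, two parents, two offspring; one
affected grandparent).  The underlying per-snp genotypes are not public, so
the dataset carries per-individual GBS totals, per-gene family means,
epsilon diplotypes and the printed APOE methylation betas — enough to
reproduce every family-level summary statistic.

J-011's total (41) is not printed as a single literal anywhere; it is forced
by the Generation II summary (mean 43.0, range 41-45, n = 2) together with
J-025's printed total of 45.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .pedigree import Individual, Pedigree, Sex

Call = tuple[str, str]


@dataclass(frozen=True)
class CoreFamily:
    pedigree: Pedigree
    totals: dict[str, int]
    generations: dict[str, int]
    carrier_flags: dict[str, bool]
    affected: tuple[str, ...]
    diplotypes: dict[str, str]
    gene_means: dict[str, float]
    total_mean_display: float  # 1-dp family mean used for the printed percentages
    apoe_betas: dict[str, float]  # only three individual betas are published
    apoe_beta_family_mean: float  # as reported; not recomputable from the three
    sibling_pair: tuple[str, str]
    sibling_abs_gene_deltas: dict[str, int]

    def epsilon_genotypes(self) -> dict[str, tuple[Call, Call]]:
        """(rs429358, rs7412) calls back-derived from the stated diplotypes.

        e3/e3 and e3/e4 are the two diplotypes present and both are
        unambiguous: e3/e3 <-> (T/T, C/C), e3/e4 <-> (C/T, C/C).
        """
        mapping = {"e3/e3": (("T", "T"), ("C", "C")), "e3/e4": (("C", "T"), ("C", "C"))}
        return {iid: mapping[d] for iid, d in self.diplotypes.items()}


def core_family() -> CoreFamily:
    """The seven-member worked-example family with its published summary data."""
    individuals = [
        Individual("J-003", Sex.FEMALE, None, None, affected=True),
        Individual("J-005", Sex.MALE, None, None),
        Individual("J-006", Sex.FEMALE, None, None),
        Individual("J-011", Sex.MALE, "J-005", "J-006"),
        # J-025 is the affected grandmother's child; the other parent is
        # outside the blood core (partial parentage).
        Individual("J-025", Sex.FEMALE, None, "J-003"),
        Individual("J-012", Sex.MALE, "J-011", "J-025"),
        Individual("J-017", Sex.MALE, "J-011", "J-025"),
    ]
    ped = Pedigree(family_id="CORE", individuals=individuals)
    totals = {
        "J-003": 39,
        "J-005": 51,
        "J-006": 54,
        "J-011": 41,
        "J-025": 45,
        "J-012": 37,
        "J-017": 61,
    }
    carriers = {"J-003", "J-025", "J-017"}
    return CoreFamily(
        pedigree=ped,
        totals=totals,
        generations={
            "J-003": 1,
            "J-005": 1,
            "J-006": 1,
            "J-011": 2,
            "J-025": 2,
            "J-012": 3,
            "J-017": 3,
        },
        carrier_flags={iid: iid in carriers for iid in totals},
        affected=("J-003",),
        diplotypes={
            iid: ("e3/e4" if iid in carriers else "e3/e3") for iid in totals
        },
        gene_means={
            "CR1": 18.1,
            "PICALM": 9.4,
            "ABCA7": 6.1,
            "CLU": 5.3,
            "BIN1": 5.0,
            "APOE": 2.9,
        },
        total_mean_display=46.9,
        apoe_betas={"J-003": 0.495, "J-005": 0.520, "J-006": 0.540},
        apoe_beta_family_mean=0.523,
        sibling_pair=("J-012", "J-017"),
        sibling_abs_gene_deltas={
            "CR1": 16,
            "PICALM": 16,
            "BIN1": 10,
            "ABCA7": 5,
            "CLU": 3,
            "APOE": 1,
        },
    )
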