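"""APOE epsilon-diplotype calling from rs429358 and rs7412.

The three common APOE isoforms are jointly encoded by two coding SNPs:

=========  =========  =======
haplotype  rs429358   rs7412
=========  =========  =======
e2         T          T
e3         T          C
e4         C          C
e1         C          T   (vanishingly rare)
=========  =========  =======

Unphased genotypes at the two sites are resolved by enumerating all
haplotype pairs consistent with both calls.  The double heterozygote
(C/T, C/T) is the single ambiguous input: both e2/e4 and e1/e3 explain it.
It is reported as e2/e4 — e1 is essentially absent from human populations —
with ``ambiguous=True`` and the alternative recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations_with_replacement
from pathlib import Path
from typing import Iterable, Mapping, Sequence

Call = tuple[str, str]

#: (rs429358 allele, rs7412 allele) per epsilon haplotype.
HAPLOTYPE_TABLE: dict[str, tuple[str, str]] = {
    "e2": ("T", "T"),
    "e3": ("T", "C"),
    "e4": ("C", "C"),
    "e1": ("C", "T"),
}

#: Canonical display order.
_ORDER = {"e2": 0, "e3": 1, "e4": 2, "e1": 3}


class ApoeError(ValueError):
    pass


@dataclass(frozen=True)
class ApoeDiplotype:
    allele1: str
    allele2: str
    ambiguous: bool
    source_genotypes: tuple[Call, Call]
    alternative: tuple[str, str] | None = None

    def __str__(self) -> str:
        return f"{self.allele1}/{self.allele2}"

    @property
    def alleles(self) -> tuple[str, str]:
        return (self.allele1, self.allele2)


def _check_call(call: Call, legal: tuple[str, str], snp: str) -> Call:
    if call is None:
        raise ApoeError(f"missing {snp} call")
    if len(call) != 2 or any(a not in legal for a in call):
        raise ApoeError(f"illegal {snp} genotype {call!r}; alleles must be in {legal}")
    return tuple(sorted(call))  # type: ignore[return-value]


def _canonical(pair: tuple[str, str]) -> tuple[str, str]:
    a, b = sorted(pair, key=_ORDER.__getitem__)
    return a, b


def call_apoe(g429358: Call, g7412: Call) -> ApoeDiplotype:
    """Resolve an unphased (rs429358, rs7412) genotype pair into a diplotype.

    Enumerates all unordered haplotype pairs whose per-site allele multisets
    match both calls.  A unique pair is returned directly; the double
    heterozygote yields {e2/e4, e1/e3} and is flagged ambiguous (reported as
    e2/e4).
    """
    g1 = _check_call(g429358, ("C", "T"), "rs429358")
    g2 = _check_call(g7412, ("C", "T"), "rs7412")
    consistent: list[tuple[str, str]] = []
    for ha, hb in combinations_with_replacement(HAPLOTYPE_TABLE, 2):
        a1, a2 = HAPLOTYPE_TABLE[ha]
        b1, b2 = HAPLOTYPE_TABLE[hb]
        if tuple(sorted((a1, b1))) == g1 and tuple(sorted((a2, b2))) == g2:
            consistent.append(_canonical((ha, hb)))
    consistent = sorted(set(consistent), key=lambda p: (_ORDER[p[0]], _ORDER[p[1]]))
    if not consistent:  # unreachable: every legal input has >= 1 explanation
        raise ApoeError(f"no haplotype pair consistent with {g1}, {g2}")
    if len(consistent) == 1:
        a, b = consistent[0]
        return ApoeDiplotype(a, b, ambiguous=False, source_genotypes=(g1, g2))
    # double heterozygote: e2/e4 preferred over e1/e3
    preferred = ("e2", "e4") if ("e2", "e4") in consistent else consistent[0]
    alternative = next(p for p in consistent if p != preferred)
    return ApoeDiplotype(
        preferred[0],
        preferred[1],
        ambiguous=True,
        source_genotypes=(g1, g2),
        alternative=alternative,
    )


def is_e4_carrier(d: ApoeDiplotype) -> bool:
    """True iff the diplotype contains at least one e4 allele."""
    return "e4" in d.alleles


def apoe_table(
    calls: Mapping[str, tuple[Call, Call]], path: str | Path | None = None
) -> "list[dict[str, object]]":
    """Call diplotypes for many samples; optionally write the report TSV.

    ``calls`` maps sample id -> (rs429358 call, rs7412 call).
    """
    rows: list[dict[str, object]] = []
    for sample, (g1, g2) in calls.items():
        d = call_apoe(g1, g2)
        rows.append(
            {
                "sample_id": sample,
                "rs429358_gt": "/".join(d.source_genotypes[0]),
                "rs7412_gt": "/".join(d.source_genotypes[1]),
                "diplotype": str(d),
                "e4_carrier": is_e4_carrier(d),
                "ambiguous": d.ambiguous,
            }
        )
    if path is not None:
        header = "sample_id\trs429358_gt\trs7412_gt\tdiplotype\te4_carrier\tambiguous"
        lines = [header] + [
            "\t".join(str(r[k]) for k in header.split("\t")) for r in rows
        ]
        Path(path).write_text("\n".join(lines) + "\n")
    return rows
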