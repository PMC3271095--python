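"""Allele-specific impact of 3'UTR SNPs on miRNA recognition elements.

A miRSNP — a SNP inside a miRNA target site — can abolish or weaken binding
of the miRNA, or create a site that is absent on the reference allele.  The
classification here is purely positional/sequence-based: both allele
versions of the UTR are re-scanned and sites anchored at the same UTR
position are compared.  The motivating case is a C>T variant whose UTR base
pairs the second seed nucleotide of a podocyte-expressed miRNA, abolishing
repression of a growth-factor gene.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

from .seed_scan import MiRNA, MRETarget, UTRRegion, find_mres

__all__ = [
    "MiRSNP",
    "Impact",
    "SeedImpact",
    "map_snp_to_mirna_position",
    "classify_impact",
]


class Impact(str, Enum):
    ABOLISHED = "abolished"
    WEAKENED = "weakened"
    CREATED = "created"
    OUTSIDE_SITE = "outside_site"


# worst-case ordering for the per-miRNA summary
_SEVERITY = {
    Impact.ABOLISHED: 3,
    Impact.CREATED: 2,
    Impact.WEAKENED: 1,
    Impact.OUTSIDE_SITE: 0,
}


@dataclass(frozen=True)
class MiRSNP:
    """A biallelic UTR variant, 1-based UTR-local coordinate."""

    snp_id: str
    utr_position: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self):
        ref = self.ref_allele.upper().replace("T", "U")
        alt = self.alt_allele.upper().replace("T", "U")
        if len(ref) != 1 or len(alt) != 1 or ref not in "ACGU" or alt not in "ACGU":
            raise ValueError(f"{self.snp_id}: alleles must be single nucleotides")
        if ref == alt:
            raise ValueError(f"{self.snp_id}: ref and alt alleles are identical")
        object.__setattr__(self, "ref_allele", ref)
        object.__setattr__(self, "alt_allele", alt)

    def validate_against(self, utr: UTRRegion) -> None:
        if not 1 <= self.utr_position <= utr.length:
            raise ValueError(
                f"{self.snp_id}: position {self.utr_position} outside UTR {utr.gene}"
            )
        found = utr.base(self.utr_position)
        if found != self.ref_allele:
            raise ValueError(
                f"{self.snp_id}: UTR {utr.gene} has {found} at {self.utr_position}, "
                f"expected ref allele {self.ref_allele}"
            )

    def swapped(self) -> "MiRSNP":
        return MiRSNP(self.snp_id, self.utr_position, self.alt_allele, self.ref_allele)


@dataclass(frozen=True)
class SeedImpact:
    """Per-site impact record plus the worst-case summary classification."""

    mirna: str
    snp_id: str
    mirna_position: int | None
    in_seed: bool
    classification: Impact
    per_site: tuple[tuple[int, Impact], ...] = ()  # (mirna_position, class) per affected site


def map_snp_to_mirna_position(snp: MiRSNP, mre: MRETarget) -> int | None:
    """The miRNA nucleotide (1-based from the 5' end of the matched prefix)
    that pairs the SNP's UTR base, or None when the SNP lies outside the site.

    The site's 3'-most UTR base (``utr_end``) pairs the first matched miRNA
    nucleotide, so the mapping is ``utr_end - utr_position + 1`` — a bijection
    between site coordinates and miRNA positions 1..k.
    """
    if mre.utr_end < mre.utr_start:
        raise ValueError("malformed MRE: end < start")
    if mre.utr_start <= snp.utr_position <= mre.utr_end:
        return mre.utr_end - snp.utr_position + 1
    return None


def classify_impact(
    snp: MiRSNP,
    mirna: MiRNA,
    utr: UTRRegion,
    min_match: int = 7,
    prefix_start: int = 1,
) -> SeedImpact:
    """Re-scan both allele versions of the UTR and classify the SNP's effect.

    Per anchor (shared ``utr_end``):

    * site on ref covering the SNP, none surviving on alt -> ``abolished``
      (the alt allele breaks pairing and the residual match falls below
      ``min_match``);
    * site on both alleles (alt match shortened but still a site) ->
      ``weakened``;
    * site only on alt -> ``created``;
    * SNP inside no site on either allele -> ``outside_site``.

    The summary classification is the worst case over affected sites
    (abolished > created > weakened > outside_site).  Swapping ref and alt
    maps abolished <-> created and fixes weakened.
    """
    snp.validate_against(utr)
    utr_ref = utr
    utr_alt = utr.with_substitution(snp.utr_position, snp.alt_allele)

    ref_sites = find_mres(mirna, utr_ref, min_match=min_match, prefix_start=prefix_start)
    alt_sites = find_mres(mirna, utr_alt, min_match=min_match, prefix_start=prefix_start)

    pos = snp.utr_position
    ref_cover = {s.utr_end: s for s in ref_sites if s.utr_start <= pos <= s.utr_end}
    alt_cover = {s.utr_end: s for s in alt_sites if s.utr_start <= pos <= s.utr_end}
    # sites at the same anchor that no longer reach the SNP still count as present
    ref_anchor = {s.utr_end: s for s in ref_sites}
    alt_anchor = {s.utr_end: s for s in alt_sites}

    seed_offset = prefix_start - 1  # prefix position -> miRNA nucleotide number
    events: list[tuple[int, Impact]] = []
    for anchor, site in sorted(ref_cover.items()):
        prefix_pos = map_snp_to_mirna_position(snp, site)
        assert prefix_pos is not None
        if anchor in alt_anchor:
            events.append((prefix_pos, Impact.WEAKENED))
        else:
            events.append((prefix_pos, Impact.ABOLISHED))
    for anchor, site in sorted(alt_cover.items()):
        prefix_pos = map_snp_to_mirna_position(snp, site)
        assert prefix_pos is not None
        if anchor in ref_anchor:
            events.append((prefix_pos, Impact.WEAKENED))
        else:
            events.append((prefix_pos, Impact.CREATED))

    if not events:
        return SeedImpact(
            mirna=mirna.name,
            snp_id=snp.snp_id,
            mirna_position=None,
            in_seed=False,
            classification=Impact.OUTSIDE_SITE,
        )

    events.sort(key=lambda e: _SEVERITY[e[1]], reverse=True)
    top_pos, top_class = events[0]
    mirna_nt = top_pos + seed_offset
    in_seed = mirna.seed_start <= mirna_nt <= mirna.seed_end
    return SeedImpact(
        mirna=mirna.name,
        snp_id=snp.snp_id,
        mirna_position=mirna_nt,
        in_seed=in_seed,
        classification=top_class,
        per_site=tuple((p + seed_offset, c) for p, c in events),
    )
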