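"""In-silico check of mismatch-primer RFLP genotyping assays.

The assay modelled here genotypes a biallelic UTR SNP by engineering a
restriction site into the PCR product: the forward primer carries a
deliberate mismatch (e.g. penultimate T->A) so that, together with one of
the two SNP alleles, amplification completes an enzyme recognition site
(BsrI, ACTGG) that the other allele does not.  Digestion then discriminates
the alleles by fragment pattern.

Only sequence logic is modelled: exact primer annealing (mismatches allowed
solely at declared engineered positions), IUPAC pattern search on both
strands, and fragment lengths from top-strand cut positions.  No
thermodynamics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .seed_scan import UTRRegion, revcomp
from .snp_impact import MiRSNP

__all__ = [
    "Primer",
    "Enzyme",
    "SiteHit",
    "DigestResult",
    "BSRI",
    "build_amplicon",
    "find_sites",
    "digest",
    "allele_discrimination",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}
_IUPAC_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "D": "H", "H": "D", "V": "B", "N": "N",
}


def _dna(seq: str, what: str) -> str:
    up = seq.upper().replace("U", "T")
    for i, ch in enumerate(up):
        if ch not in "ACGT":
            raise ValueError(f"non-nucleotide character {seq[i]!r} at position {i + 1} in {what}")
    return up


@dataclass(frozen=True)
class Primer:
    """A PCR primer, 5'->3'.  ``engineered_mismatch_offset`` counts from the
    3' end (1 = terminal base, 2 = penultimate) and marks the single position
    where the primer is allowed to differ from the template by design."""

    name: str
    sequence: str
    engineered_mismatch_offset: int | None = None

    def __post_init__(self):
        object.__setattr__(self, "sequence", _dna(self.sequence, f"primer {self.name}"))
        if len(self.sequence) < 15:
            raise ValueError(f"primer {self.name}: length must be >= 15")
        off = self.engineered_mismatch_offset
        if off is not None and not 1 <= off <= len(self.sequence):
            raise ValueError(f"primer {self.name}: mismatch offset outside primer")

    @property
    def allowed_mismatch_index(self) -> int | None:
        """0-based index into the primer sequence, or None."""
        if self.engineered_mismatch_offset is None:
            return None
        return len(self.sequence) - self.engineered_mismatch_offset


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition pattern plus cut offsets
    relative to the 3' end of the pattern (top strand) and its complement."""

    name: str
    recognition: str
    cut_offset_top: int = 0
    cut_offset_bottom: int = 0

    def __post_init__(self):
        pat = self.recognition.upper().replace("U", "T")
        if not pat or any(ch not in _IUPAC for ch in pat):
            raise ValueError(f"enzyme {self.name}: invalid IUPAC pattern {self.recognition!r}")
        object.__setattr__(self, "recognition", pat)


# BsrI: ACTGG(1/-1) — top-strand cut one base past the pattern.
BSRI = Enzyme("BsrI", "ACTGG", cut_offset_top=1, cut_offset_bottom=-1)


@dataclass(frozen=True)
class SiteHit:
    """A recognition-site match in top-strand coordinates (1-based, inclusive)."""

    start: int
    end: int
    strand: str  # '+' top, '-' bottom

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class DigestResult:
    allele: str
    site_positions: tuple[SiteHit, ...]
    fragment_lengths: tuple[int, ...]


def _footprints(template: str, probe: str, allowed: int | None) -> list[int]:
    """0-based start positions where probe matches template, mismatching only
    at the allowed probe index (if any)."""
    hits = []
    m = len(probe)
    for s in range(len(template) - m + 1):
        ok = True
        for i in range(m):
            if template[s + i] != probe[i] and i != allowed:
                ok = False
                break
        if ok:
            hits.append(s)
    return hits


def build_amplicon(template: UTRRegion, fwd: Primer, rev: Primer) -> str:
    """The PCR product: primer sequences override the template inside their
    footprints (that is how an engineered mismatch enters the amplicon).

    The forward primer must match the template sense strand and the reverse
    primer's reverse complement the downstream template, each at exactly one
    position.
    """
    tpl = template.sequence.replace("U", "T")
    fwd_hits = _footprints(tpl, fwd.sequence, fwd.allowed_mismatch_index)
    if len(fwd_hits) != 1:
        raise ValueError(
            f"forward primer {fwd.name}: {len(fwd_hits)} footprint(s) at "
            f"{[h + 1 for h in fwd_hits]}; need exactly one"
        )
    rev_probe = revcomp(rev.sequence)
    allowed_rc = (
        None
        if rev.allowed_mismatch_index is None
        else len(rev.sequence) - 1 - rev.allowed_mismatch_index
    )
    rev_hits = [h for h in _footprints(tpl, rev_probe, allowed_rc) if h > fwd_hits[0]]
    if len(rev_hits) != 1:
        raise ValueError(
            f"reverse primer {rev.name}: {len(rev_hits)} downstream footprint(s) at "
            f"{[h + 1 for h in rev_hits]}; need exactly one"
        )
    f0, r0 = fwd_hits[0], rev_hits[0]
    if r0 < f0 + len(fwd.sequence):
        raise ValueError("primer footprints overlap")
    middle = tpl[f0 + len(fwd.sequence) : r0]
    return fwd.sequence + middle + rev_probe


def find_sites(seq: str, enzyme: Enzyme) -> list[SiteHit]:
    """All recognition-site matches on both strands, in top-strand coordinates.

    Bottom-strand matches are found by searching the reverse complement of
    the IUPAC pattern on the top strand.  Overlapping occurrences are all
    reported; results sorted by start.
    """
    s = _dna(seq, "sequence")
    hits: list[SiteHit] = []
    pat_top = "".join(_IUPAC[ch] for ch in enzyme.recognition)
    m = len(enzyme.recognition)
    for match in re.finditer(f"(?=({pat_top}))", s):
        hits.append(SiteHit(start=match.start() + 1, end=match.start() + m, strand="+"))
    rc_pattern = "".join(_IUPAC_COMPLEMENT[ch] for ch in reversed(enzyme.recognition))
    if rc_pattern != enzyme.recognition:  # palindromic patterns hit both strands at once
        pat_bot = "".join(_IUPAC[ch] for ch in rc_pattern)
        for match in re.finditer(f"(?=({pat_bot}))", s):
            hits.append(SiteHit(start=match.start() + 1, end=match.start() + m, strand="-"))
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _top_cut_positions(seq_len: int, hits: list[SiteHit], enzyme: Enzyme) -> list[int]:
    """Top-strand cut positions: a cut 'after position c' separates c and c+1.

    For a '+' hit ending at e the cut is after e + cut_offset_top; for a '-'
    hit starting at s the geometry mirrors to a cut after
    s - cut_offset_top - 1.  Cuts falling outside the molecule are dropped.
    """
    cuts = set()
    for h in hits:
        c = h.end + enzyme.cut_offset_top if h.strand == "+" else h.start - enzyme.cut_offset_top - 1
        if 1 <= c < seq_len:
            cuts.add(c)
    return sorted(cuts)


def digest(seq: str, enzyme: Enzyme, allele: str = "") -> DigestResult:
    """Cut a linear molecule; fragment lengths always sum to its length."""
    s = _dna(seq, "sequence")
    hits = find_sites(s, enzyme)
    cuts = _top_cut_positions(len(s), hits, enzyme)
    bounds = [0] + cuts + [len(s)]
    frags = tuple(b - a for a, b in zip(bounds, bounds[1:]))
    return DigestResult(allele=allele, site_positions=tuple(hits), fragment_lengths=frags)


def allele_discrimination(
    template: UTRRegion,
    snp: MiRSNP,
    fwd: Primer,
    rev: Primer,
    enzyme: Enzyme,
) -> tuple[DigestResult, DigestResult, bool]:
    """Digest both allele amplicons; discriminate iff the fragment multisets differ.

    The SNP must fall inside the amplicon but not under a primer footprint
    (a primer would overwrite it — except at the declared engineered
    position, which is the design trick this assay relies on).
    """
    snp.validate_against(template)
    tpl = template.sequence.replace("U", "T")
    f0 = _footprints(tpl, fwd.sequence, fwd.allowed_mismatch_index)
    rev_probe = revcomp(rev.sequence)
    allowed_rc = (
        None
        if rev.allowed_mismatch_index is None
        else len(rev.sequence) - 1 - rev.allowed_mismatch_index
    )
    if len(f0) != 1:
        raise ValueError(f"forward primer {fwd.name}: footprint not unique on template")
    r0 = [h for h in _footprints(tpl, rev_probe, allowed_rc) if h > f0[0]]
    if len(r0) != 1:
        raise ValueError(f"reverse primer {rev.name}: footprint not unique downstream")
    pos0 = snp.utr_position - 1  # 0-based on template
    fwd_span = range(f0[0], f0[0] + len(fwd.sequence))
    rev_span = range(r0[0], r0[0] + len(rev_probe))
    fwd_design = None if fwd.allowed_mismatch_index is None else f0[0] + fwd.allowed_mismatch_index
    if (pos0 in fwd_span and pos0 != fwd_design) or pos0 in rev_span:
        raise ValueError(
            f"{snp.snp_id}: SNP at {snp.utr_position} lies under a primer footprint"
        )
    if not f0[0] <= pos0 < r0[0] + len(rev_probe):
        raise ValueError(f"{snp.snp_id}: SNP at {snp.utr_position} outside the amplicon")

    results = []
    for allele in (snp.ref_allele, snp.alt_allele):
        allele_dna = allele.replace("U", "T")
        tmpl_allele = template.with_substitution(snp.utr_position, allele_dna)
        amplicon = build_amplicon(tmpl_allele, fwd, rev)
        results.append(digest(amplicon, enzyme, allele=allele_dna))
    ref_res, alt_res = results
    discriminates = sorted(ref_res.fragment_lengths) != sorted(alt_res.fragment_lengths)
    return ref_res, alt_res, discriminates
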