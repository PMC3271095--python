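"""Synthetic fixtures with the statistical structure the analyses assume.

Everything here is a generator with certified ground truth, so each pipeline
stage is testable without any external data: Hardy-Weinberg genotype
sampling, two-cohort carrier status under a dominant-model odds ratio, UTR
sequences with planted seed-complementary sites (and optionally a planted
miRSNP with a known impact label), two-group normalized reporter
measurements, and a synthetic template for the mismatch-primer RFLP assay.

All generators are deterministic given (spec, seed).  Per-call PRNG streams
are derived from (seed, call-tag) so adding a generator never perturbs the
fixtures of another.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .association import CohortGenotypes
from .seed_scan import MiRNA, UTRRegion, revcomp
from .snp_impact import Impact, MiRSNP

__all__ = [
    "SimCohortSpec",
    "SimUTRSpec",
    "SimReporterSpec",
    "rng_for",
    "random_mirna",
    "simulate_genotypes",
    "simulate_case_control",
    "simulate_utr",
    "simulate_reporter",
    "make_rflp_fixture",
    "brute_force_sites",
]

_COMP_RNA = {"A": "U", "U": "A", "G": "C", "C": "G"}


def rng_for(seed: int, tag: str) -> np.random.Generator:
    """An independent PRNG stream for (seed, tag)."""
    tag_key = zlib.crc32(tag.encode())
    return np.random.default_rng(np.random.SeedSequence([int(seed), tag_key]))


@dataclass(frozen=True)
class SimCohortSpec:
    """Two-cohort case-control generator parameters.

    The study conditions mirror the nephropathy cohorts: 45 mild and 33
    severe patients, minor-allele frequency giving a ~23% carrier rate, a
    carrier odds ratio of 3.7 for the severe outcome, and a baseline
    (non-carrier) severity rate of 0.42, the severe fraction of the cohort.
    """

    n1: int = 45  # mild / reference cohort
    n2: int = 33  # severe / case cohort
    allele_freq: float = 0.1225  # gives P(carrier) = 1 - (1-q)^2 ~ 0.23
    or_carrier: float = 3.7
    baseline_rate: float = 0.42
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.allele_freq < 0.5:
            raise ValueError("allele_freq must be in (0, 0.5)")
        if self.or_carrier <= 0:
            raise ValueError("or_carrier must be positive")
        if self.n1 < 1 or self.n2 < 1:
            raise ValueError("cohort sizes must be >= 1")
        if not 0.0 < self.baseline_rate < 1.0:
            raise ValueError("baseline_rate must be in (0, 1)")


@dataclass(frozen=True)
class SimUTRSpec:
    """A UTR with planted MREs and optionally a planted miRSNP.

    ``planted_mres``: (MiRNA, utr_start, match_len) triples; sites must not
    overlap.  ``snp_spec``: (utr_position, truth_label) — alleles are chosen
    by the generator to realise the label and are reported in the truth
    table.
    """

    length: int = 500
    planted_mres: tuple = ()
    snp_spec: tuple | None = None  # (position, Impact)
    absent_mirnas: tuple = ()  # miRNAs certified to have NO site >= min_match
    min_match: int = 7
    seed: int = 0

    def __post_init__(self):
        spans = []
        for mirna, start, k in self.planted_mres:
            if k > len(mirna.sequence):
                raise ValueError(f"match_len {k} exceeds miRNA {mirna.name} length")
            if not (1 <= start and start + k - 1 <= self.length):
                raise ValueError(f"planted site [{start}, {start + k - 1}] outside UTR")
            spans.append((start, start + k - 1))
        spans.sort()
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise ValueError("planted sites overlap")


@dataclass(frozen=True)
class SimReporterSpec:
    """Two-group normalized reporter (luciferase) measurements, in percent
    of control.  Defaults are the observed allele contrast: an active
    (repressed) construct at 47.14 +/- 0.42 SEM and an inactive one at
    90.56 +/- 3.8 SEM, n = 3 per group."""

    mean_active: float = 47.14
    mean_inactive: float = 90.56
    sem_active: float = 0.42
    sem_inactive: float = 3.8
    n: int = 3
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.mean_active <= 150 and 0 < self.mean_inactive <= 150):
            raise ValueError("group means must be in (0, 150]")
        if self.n < 3:
            raise ValueError("n per group must be >= 3")
        if self.sem_active < 0 or self.sem_inactive < 0:
            raise ValueError("SEMs must be non-negative")


def simulate_genotypes(
    n: int,
    allele_freq: float,
    seed: int | np.random.Generator = 0,
    label: str = "sim",
) -> CohortGenotypes:
    """Sample n genotypes from Hardy-Weinberg proportions at frequency q."""
    if not 0.0 <= allele_freq <= 1.0:
        raise ValueError("allele_freq must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else rng_for(seed, "genotypes")
    q = allele_freq
    probs = [(1 - q) ** 2, 2 * q * (1 - q), q**2]
    cc, ct, tt = rng.multinomial(n, probs)
    return CohortGenotypes(label=label, n_CC=int(cc), n_CT=int(ct), n_TT=int(tt))


def _severity_probs(spec: SimCohortSpec) -> tuple[float, float]:
    """(P(severe | non-carrier), P(severe | carrier)) under a logistic
    carrier model: carrier odds = or_carrier * baseline odds."""
    odds0 = spec.baseline_rate / (1 - spec.baseline_rate)
    odds1 = spec.or_carrier * odds0
    return odds0 / (1 + odds0), odds1 / (1 + odds1)


def simulate_case_control(
    spec: SimCohortSpec,
    conditioned: bool = True,
) -> tuple[CohortGenotypes, CohortGenotypes]:
    """Draw (mild, severe) cohorts with carrier-dependent severity.

    Genotypes follow Hardy-Weinberg sampling; the severe outcome is Bernoulli
    with carrier odds ``or_carrier`` times the baseline odds.  In
    ``conditioned`` mode individuals are drawn until the two cohorts reach
    exactly n1 and n2 (outcome-conditioned sampling, the case-control
    design); otherwise n1 + n2 individuals are drawn and realized cohort
    sizes are returned.
    """
    rng = rng_for(spec.seed, "case_control")
    q = spec.allele_freq
    geno_probs = np.array([(1 - q) ** 2, 2 * q * (1 - q), q**2])
    p0, p1 = _severity_probs(spec)

    mild = np.zeros(3, dtype=int)
    severe = np.zeros(3, dtype=int)
    if conditioned:
        need1, need2 = spec.n1, spec.n2
        guard = 0
        while need1 > 0 or need2 > 0:
            guard += 1
            if guard > 10_000:
                raise RuntimeError("conditioned sampling failed to fill cohorts")
            batch = max(256, 4 * (need1 + need2))
            geno = rng.choice(3, size=batch, p=geno_probs)
            carrier = geno > 0
            sev = rng.random(batch) < np.where(carrier, p1, p0)
            take_mild = geno[~sev][:need1]
            take_sev = geno[sev][:need2]
            mild += np.bincount(take_mild, minlength=3)
            severe += np.bincount(take_sev, minlength=3)
            need1 -= len(take_mild)
            need2 -= len(take_sev)
    else:
        n = spec.n1 + spec.n2
        geno = rng.choice(3, size=n, p=geno_probs)
        carrier = geno > 0
        sev = rng.random(n) < np.where(carrier, p1, p0)
        for g, s in zip(geno, sev):
            (severe if s else mild)[g] += 1
        if mild.sum() == 0 or severe.sum() == 0:
            raise RuntimeError(
                "degenerate draw: one cohort is empty; use conditioned mode or larger n"
            )
    mild_c = CohortGenotypes("sim_mild", int(mild[0]), int(mild[1]), int(mild[2]))
    severe_c = CohortGenotypes("sim_severe", int(severe[0]), int(severe[1]), int(severe[2]))
    return mild_c, severe_c


def random_mirna(rng: np.random.Generator, name: str = "sim-mir", length: int = 22) -> MiRNA:
    seq = "".join(rng.choice(list("ACGU"), size=length))
    return MiRNA(name=name, sequence=seq)


def brute_force_sites(
    utr_seq: str,
    mirna_seq: str,
    min_match: int,
    prefix_start: int = 1,
) -> list[tuple[int, int, int]]:
    """Naive reference scanner: (utr_start, utr_end, k) of maximal prefix
    matches, by direct string comparison at every anchor.  Kept deliberately
    independent of the incremental scanner it certifies."""
    utr = utr_seq.upper().replace("T", "U")
    prefix = mirna_seq.upper().replace("T", "U")[prefix_start - 1 :]
    L = len(utr)
    out = []
    for end in range(1, L + 1):
        k = 0
        for klen in range(1, min(len(prefix), end) + 1):
            if utr[end - klen : end] == revcomp(prefix[:klen]):
                k = klen
        if k >= min_match:
            out.append((end - k + 1, end, k))
    return out


def _plant(seq: list[str], start: int, site: str) -> None:
    seq[start - 1 : start - 1 + len(site)] = list(site)


def simulate_utr(spec: SimUTRSpec, max_tries: int = 200):
    """Generate a certified UTR fixture.

    Background is i.i.d. uniform; each planted (miRNA, start, k) is written
    as the exact reverse complement of the miRNA prefix.  Rejection
    sampling guarantees that for every involved miRNA the *only* sites of
    length >= min_match are the planted ones (verified by the brute-force
    scanner), so absence elsewhere is certified, not merely probable.

    Returns (UTRRegion, truth) where truth maps:
      "sites"   -> [(mirna_name, utr_start, utr_end, k), ...]
      "snp"     -> planted MiRSNP or None
      "label"   -> planted Impact or None
    """
    rng = rng_for(spec.seed, "utr")
    mirnas = [m for m, _, _ in spec.planted_mres] + list(spec.absent_mirnas)
    snp = None
    label = None
    if spec.snp_spec is not None:
        snp_pos, label = spec.snp_spec
        label = Impact(label)

    for _ in range(max_tries):
        seq = list(rng.choice(list("ACGU"), size=spec.length))
        expected: dict[str, list[tuple[int, int, int]]] = {m.name: [] for m in mirnas}
        for mirna, start, k in spec.planted_mres:
            _plant(seq, start, revcomp(mirna.sequence[:k]))
            expected[mirna.name].append((start, start + k - 1, k))

        snp_obj = None
        if spec.snp_spec is not None:
            snp_obj = _plant_snp(seq, spec, rng)
            if snp_obj is None:
                continue  # label unrealisable on this background, redraw

        ref_seq = "".join(seq)
        ok = all(
            brute_force_sites(ref_seq, m.sequence, spec.min_match) == sorted(expected[m.name])
            for m in mirnas
        )
        if ok and snp_obj is not None:
            ok = _certify_snp(ref_seq, snp_obj, spec, label)
        if ok:
            utr = UTRRegion(gene=f"simUTR_seed{spec.seed}", sequence=ref_seq)
            truth = {
                "sites": [
                    (m.name, s, e, k)
                    for m in mirnas
                    for (s, e, k) in expected[m.name]
                ],
                "snp": snp_obj,
                "label": label,
            }
            return utr, truth
    raise RuntimeError("could not generate a certified fixture; spec may be unsatisfiable")


def _containing_site(spec: SimUTRSpec, pos: int):
    for mirna, start, k in spec.planted_mres:
        if start <= pos <= start + k - 1:
            return mirna, start, k
    return None


def _plant_snp(seq: list[str], spec: SimUTRSpec, rng: np.random.Generator) -> MiRSNP | None:
    """Choose ref/alt alleles at the requested position realising the label.

    abolished/weakened: position must sit inside a planted site; ref is the
    planted (complementary) base and alt any base breaking the pair.
    created: position must be outside all planted sites; the generator
    plants an alt-complete site by writing a one-mismatch site around the
    position (mismatch exactly at the SNP).  outside_site: any position
    away from the planted sites; alt is any other base.
    """
    pos, label = spec.snp_spec
    label = Impact(label)
    hit = _containing_site(spec, pos)
    if label in (Impact.ABOLISHED, Impact.WEAKENED):
        if hit is None:
            raise ValueError(f"label {label.value} needs the SNP inside a planted site")
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGU" if b != ref])
        return MiRSNP("sim_snp", pos, ref, str(alt))
    if label is Impact.OUTSIDE_SITE:
        if hit is not None:
            raise ValueError("label outside_site needs the SNP outside planted sites")
        ref = seq[pos - 1]
        alt = rng.choice([b for b in "ACGU" if b != ref])
        return MiRSNP("sim_snp", pos, ref, str(alt))
    if label is Impact.CREATED:
        if hit is not None:
            raise ValueError("label created needs the SNP outside planted (ref) sites")
        if not spec.planted_mres:
            raise ValueError("label created needs a miRNA to gain a site for")
        mirna = spec.planted_mres[0][0]
        k = spec.planted_mres[0][2]
        # write the site so that the SNP position pairs seed nucleotide 2
        end = pos + 1
        start = end - k + 1
        if start < 1 or end > spec.length:
            raise ValueError("created-site span outside UTR")
        for _, s, kk in spec.planted_mres:
            if not (start + k - 1 < s or s + kk - 1 < start):
                return None  # collides with a planted site on this layout
        site = revcomp(mirna.sequence[:k])
        _plant(seq, start, site)
        good = seq[pos - 1]  # complementary base completing the site
        ref = str(rng.choice([b for b in "ACGU" if b != good]))
        seq[pos - 1] = ref  # ref allele carries the mismatch
        return MiRSNP("sim_snp", pos, ref, good)
    raise AssertionError(label)


def _certify_snp(ref_seq: str, snp: MiRSNP, spec: SimUTRSpec, label: Impact) -> bool:
    """Check with the brute-force scanner that both allele sequences realise
    the planted label (site lost / shortened / gained / untouched)."""
    alt_seq = ref_seq[: snp.utr_position - 1] + snp.alt_allele + ref_seq[snp.utr_position :]
    pos = snp.utr_position

    def covering(seqstr, mirna):
        return [
            (s, e, k)
            for (s, e, k) in brute_force_sites(seqstr, mirna.sequence, spec.min_match)
            if s <= pos <= e
        ]

    mirnas = [m for m, _, _ in spec.planted_mres]
    if label is Impact.OUTSIDE_SITE:
        return all(not covering(ref_seq, m) and not covering(alt_seq, m) for m in mirnas)
    mirna = mirnas[0]
    ref_cov = covering(ref_seq, mirna)
    alt_cov = covering(alt_seq, mirna)
    ref_anchors = {e for (_, e, _) in brute_force_sites(ref_seq, mirna.sequence, spec.min_match)}
    alt_anchors = {e for (_, e, _) in brute_force_sites(alt_seq, mirna.sequence, spec.min_match)}
    if label is Impact.ABOLISHED:
        return bool(ref_cov) and all(e not in alt_anchors for (_, e, _) in ref_cov)
    if label is Impact.WEAKENED:
        return bool(ref_cov) and all(e in alt_anchors for (_, e, _) in ref_cov)
    if label is Impact.CREATED:
        return bool(alt_cov) and all(e not in ref_anchors for (_, e, _) in alt_cov)
    raise AssertionError(label)


def simulate_reporter(spec: SimReporterSpec) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian reporter draws per group with sd = SEM * sqrt(n).

    Returns (active, inactive) arrays of length n, in percent of control.
    """
    rng = rng_for(spec.seed, "reporter")
    sd_a = spec.sem_active * np.sqrt(spec.n)
    sd_i = spec.sem_inactive * np.sqrt(spec.n)
    active = rng.normal(spec.mean_active, sd_a, size=spec.n)
    inactive = rng.normal(spec.mean_inactive, sd_i, size=spec.n)
    return active, inactive


def make_rflp_fixture(seed: int = 0, flank: int = 120):
    """A synthetic genotyping template around the published primer pair.

    Builds a template carrying both primer footprints (the forward footprint
    restores the wild-type T at the engineered penultimate position), the
    SNP base immediately downstream of the forward primer, and random flanks
    certified free of additional BsrI sites on either strand of either
    allele amplicon.  Returns (template, snp, fwd, rev).
    """
    from .rflp import BSRI, Primer, build_amplicon, find_sites

    fwd = Primer(
        "fwd_bsri",
        "CAAAGTGTAACAGATATCAGTGTCTCCCCGTGTCCTCTCCCAG",
        engineered_mismatch_offset=2,
    )
    rev = Primer("rev", "GCTTTGCTAATACCTTCTCCAGACTGTCCTCTGCTGCACTGA")
    # template sense strand: wild-type T where the primer engineers an A
    fwd_tpl = fwd.sequence[:-2] + "T" + fwd.sequence[-1]
    rev_tpl = revcomp(rev.sequence)
    rng = rng_for(seed, "rflp_template")
    for _ in range(500):
        left = "".join(rng.choice(list("ACGT"), size=flank))
        mid = "".join(rng.choice(list("ACGT"), size=40))
        right = "".join(rng.choice(list("ACGT"), size=flank))
        # SNP base (ref C) immediately after the forward footprint
        tpl_seq = left + fwd_tpl + "C" + mid + rev_tpl + right
        template = UTRRegion("sim_template", tpl_seq)
        snp = MiRSNP("simC>T", len(left) + len(fwd_tpl) + 1, "C", "T")
        try:
            ok = True
            for allele in ("C", "T"):
                amp = build_amplicon(
                    template.with_substitution(snp.utr_position, allele), fwd, rev
                )
                n_sites = len(find_sites(amp, BSRI))
                if allele == "C" and n_sites != 0:
                    ok = False
                if allele == "T" and n_sites != 1:
                    ok = False
        except ValueError:
            ok = False
        if ok:
            return template, snp, fwd, rev
    raise RuntimeError("could not build a certified RFLP fixture")
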