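"""miRNA recognition-element (MRE) scanning on 3'UTR sequences.

A mature miRNA recognises its target mainly through Watson-Crick pairing of
its 5' end (the "seed", nucleotides 2-8) to a complementary stretch on the
mRNA 3'UTR.  This module finds such sites by exact complementarity to the
miRNA 5'-prefix, attaches a Poisson enrichment p-value (probability of the
prefix pairing a UTR of that length and composition by chance) and applies a
multi-predictor consensus filter.

Conventions
-----------
* All coordinates are 1-based, inclusive, ascending on the UTR sense strand.
  The site's 3'-most UTR base pairs the miRNA 5'-most matched nucleotide, so
  descending (START > END) report coordinates used by some prediction tools
  map to ``utr_start = END, utr_end = START``.
* T and U are interchangeable; matching is strict Watson-Crick (no G:U
  wobble).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

__all__ = [
    "MiRNA",
    "UTRRegion",
    "MRETarget",
    "PoissonModel",
    "revcomp",
    "find_mres",
    "poisson_pvalue",
    "annotate_pvalues",
    "consensus_filter",
]

_COMPLEMENT_RNA = {"A": "U", "U": "A", "G": "C", "C": "G"}


def _normalize(seq: str, *, what: str = "sequence") -> str:
    """Uppercase and convert to the RNA alphabet (T -> U); reject junk."""
    up = seq.upper().replace("T", "U")
    for i, ch in enumerate(up):
        if ch not in "ACGU":
            raise ValueError(
                f"non-nucleotide character {seq[i]!r} at position {i + 1} in {what}"
            )
    return up


@dataclass(frozen=True)
class MiRNA:
    """A mature miRNA, sequence written 5'->3'.

    ``seed_start``/``seed_end`` delimit the canonical seed (defaults 2-8,
    1-based from the 5' end).
    """

    name: str
    sequence: str
    seed_start: int = 2
    seed_end: int = 8

    def __post_init__(self):
        norm = _normalize(self.sequence, what=f"miRNA {self.name}")
        object.__setattr__(self, "sequence", norm)
        if not self.sequence:
            raise ValueError(f"miRNA {self.name}: empty sequence")
        if not (1 <= self.seed_start < self.seed_end):
            raise ValueError(f"miRNA {self.name}: invalid seed bounds")
        if len(self.sequence) < self.seed_end:
            raise ValueError(
                f"miRNA {self.name}: sequence shorter than seed_end={self.seed_end}"
            )


@dataclass(frozen=True)
class UTRRegion:
    """A 3'UTR (or any UTR-local) sequence, 5'->3', 1-based coordinates."""

    gene: str
    sequence: str

    def __post_init__(self):
        object.__setattr__(
            self, "sequence", _normalize(self.sequence, what=f"UTR {self.gene}")
        )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def base(self, position: int) -> str:
        """1-based access."""
        if not 1 <= position <= self.length:
            raise IndexError(f"position {position} outside UTR {self.gene} (length {self.length})")
        return self.sequence[position - 1]

    def with_substitution(self, position: int, base: str) -> "UTRRegion":
        b = _normalize(base, what="substituted base")
        s = self.sequence
        return UTRRegion(self.gene, s[: position - 1] + b + s[position:])


@dataclass(frozen=True)
class MRETarget:
    """A predicted miRNA recognition element on a UTR.

    ``utr_end`` pairs the first matched miRNA nucleotide; ``match_len`` is
    the length of the matched miRNA 5'-prefix, ``matched_prefix`` the prefix
    itself (RNA alphabet, 5'->3').
    """

    gene: str
    mirna: str
    utr_start: int
    utr_end: int
    match_len: int
    matched_prefix: str
    pvalue: float | None = None
    sources: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.utr_end < self.utr_start:
            raise ValueError("MRETarget: utr_end < utr_start (coordinates must ascend)")
        if self.utr_end - self.utr_start + 1 != self.match_len:
            raise ValueError("MRETarget: span does not equal match_len")
        if self.pvalue is not None and not 0.0 < self.pvalue <= 1.0:
            raise ValueError("MRETarget: pvalue outside (0, 1]")

    @property
    def start_reported(self) -> int:
        """Descending-convention START (pairs miRNA nt 1), as some tools print."""
        return self.utr_end

    @property
    def end_reported(self) -> int:
        return self.utr_start


def revcomp(seq: str) -> str:
    """Strict Watson-Crick reverse complement.

    Accepts DNA or RNA (mixed case); the output uses U if the input did,
    else T.  Involution: ``revcomp(revcomp(s)) == s`` up to normalization.
    """
    is_dna = "T" in seq.upper() and "U" not in seq.upper()
    norm = _normalize(seq)
    rc = "".join(_COMPLEMENT_RNA[ch] for ch in reversed(norm))
    return rc.replace("U", "T") if is_dna else rc


def find_mres(
    mirna: MiRNA,
    utr: UTRRegion,
    min_match: int = 7,
    prefix_start: int = 1,
) -> list[MRETarget]:
    """Scan a UTR for sites complementary to the miRNA 5'-prefix.

    At every UTR anchor position (the base pairing the first matched miRNA
    nucleotide) the longest consecutive Watson-Crick match is taken; anchors
    reaching ``min_match`` are reported, sorted by ``utr_start``.  Sub-matches
    of a longer match at the same anchor are not reported separately.

    ``prefix_start`` selects where on the miRNA the matched prefix begins
    (1 = the 5' terminus, 2 = the first seed base).
    """
    if min_match < 6:
        raise ValueError("min_match must be >= 6")
    if prefix_start not in (1, 2):
        raise ValueError("prefix_start must be 1 or 2")
    prefix = mirna.sequence[prefix_start - 1 :]
    if not prefix:
        raise ValueError(f"miRNA {mirna.name}: no sequence downstream of prefix_start")
    comp = [_COMPLEMENT_RNA[ch] for ch in prefix]
    seq = utr.sequence
    L = len(seq)
    out: list[MRETarget] = []
    for anchor in range(1, L + 1):  # 1-based utr_end candidate
        k = 0
        while k < len(comp) and anchor - k >= 1 and seq[anchor - 1 - k] == comp[k]:
            k += 1
        if k >= min_match:
            out.append(
                MRETarget(
                    gene=utr.gene,
                    mirna=mirna.name,
                    utr_start=anchor - k + 1,
                    utr_end=anchor,
                    match_len=k,
                    matched_prefix=prefix[:k],
                )
            )
    out.sort(key=lambda t: (t.utr_start, t.utr_end))
    return out


@dataclass(frozen=True)
class PoissonModel:
    """Background model for chance occurrence of a k-nt pairing in a UTR.

    lam is the expected number of chance sites: (L - k + 1) times the product
    of per-nucleotide background probabilities over the matched site.
    """

    lam: float
    background: dict[str, float]
    m_obs: int


def _background_probs(utr: UTRRegion, background: str | dict[str, float]) -> dict[str, float]:
    if isinstance(background, dict):
        probs = {k.upper().replace("T", "U"): v for k, v in background.items()}
    elif background == "uniform":
        probs = {b: 0.25 for b in "ACGU"}
    elif background == "empirical":
        if utr.length == 0:
            probs = {b: 0.25 for b in "ACGU"}
        else:
            probs = {b: utr.sequence.count(b) / utr.length for b in "ACGU"}
    else:
        raise ValueError(f"unknown background {background!r}")
    total = sum(probs.values())
    if not np.isclose(total, 1.0):
        raise ValueError("background probabilities must sum to 1")
    return probs


def poisson_pvalue(
    utr: UTRRegion,
    k: int,
    m_obs: int,
    background: str | dict[str, float] = "uniform",
    site: str | None = None,
) -> tuple[float, PoissonModel]:
    """P(X >= m_obs) for X ~ Poisson(lam), the chance-site count.

    ``site`` (the matched UTR subsequence) refines lam under a non-uniform
    background; with the uniform default every k-mer has probability 4^-k.
    Returns 1.0 when ``m_obs`` is 0.  ``k`` larger than the UTR is degenerate
    (no site can exist): p = 1 with a warning.
    """
    L = utr.length
    probs = _background_probs(utr, background)
    if k > L:
        warnings.warn(f"match length {k} exceeds UTR length {L}; p-value degenerate at 1")
        model = PoissonModel(lam=0.0, background=probs, m_obs=m_obs)
        return 1.0, model
    if site is not None:
        site_n = _normalize(site, what="site")
        if len(site_n) != k:
            raise ValueError("site length must equal k")
        per_site = float(np.prod([probs[ch] for ch in site_n]))
    elif probs == {b: 0.25 for b in "ACGU"}:
        per_site = 0.25**k
    else:
        raise ValueError("a site sequence is required under a non-uniform background")
    lam = (L - k + 1) * per_site
    model = PoissonModel(lam=lam, background=probs, m_obs=m_obs)
    if m_obs <= 0:
        return 1.0, model
    # survival function at m_obs - 1 gives P(X >= m_obs)
    return float(stats.poisson.sf(m_obs - 1, lam)), model


def annotate_pvalues(
    targets: list[MRETarget],
    utr: UTRRegion,
    background: str | dict[str, float] = "uniform",
) -> list[MRETarget]:
    """Attach per-pair Poisson enrichment p-values to scanned targets.

    For each miRNA the observed count m_obs is the number of its sites on
    this UTR; each site's p-value uses its own match length and sequence.
    """
    counts: dict[str, int] = {}
    for t in targets:
        counts[t.mirna] = counts.get(t.mirna, 0) + 1
    out = []
    for t in targets:
        site_seq = utr.sequence[t.utr_start - 1 : t.utr_end]
        p, _ = poisson_pvalue(utr, t.match_len, counts[t.mirna], background, site=site_seq)
        out.append(replace(t, pvalue=p))
    return out


def consensus_filter(
    targets: list[MRETarget],
    min_sources: int = 5,
    alpha: float = 0.05,
) -> list[MRETarget]:
    """Keep targets supported by >= min_sources predictors with p < alpha.

    Order-stable; output is always a subset of the input, hence idempotent.
    Targets with no p-value attached are dropped (they cannot pass p < alpha).
    """
    return [
        t
        for t in targets
        if len(t.sources) >= min_sources and t.pvalue is not None and t.pvalue < alpha
    ]


def attach_sources(targets: list[MRETarget], hits) -> list[MRETarget]:
    """Merge a predictor hit table (columns gene, mirna, source) onto targets."""
    by_pair: dict[tuple[str, str], set[str]] = {}
    for row in hits.itertuples(index=False):
        by_pair.setdefault((row.gene, row.mirna), set()).add(row.source)
    return [
        replace(t, sources=frozenset(by_pair.get((t.gene, t.mirna), set())))
        for t in targets
    ]
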