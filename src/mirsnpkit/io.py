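"""Readers and writers for the pipeline's plain-text formats.

FASTA goes through Biopython, tables through pandas, VCF through pysam.
Internal coordinates are 1-based inclusive throughout; conversion to 0-based
half-open happens only at the BED writer.  Report writers prepend a header
block (version, seed, parameters) so a run is reproducible from its output
alone.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import pandas as pd
from Bio import SeqIO

from . import __version__
from .association import CohortGenotypes, ContingencyTable2x2
from .rflp import Enzyme
from .seed_scan import MiRNA, MRETarget, UTRRegion
from .snp_impact import MiRSNP

__all__ = [
    "read_fasta",
    "read_mirnas",
    "read_utrs",
    "read_snp_table",
    "read_snps_vcf",
    "read_genotype_table",
    "read_carrier_table",
    "read_predictor_hits",
    "read_published_sites",
    "read_enzyme_table",
    "write_mre_table",
    "write_bed6",
    "write_report",
    "read_report",
]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """(name, sequence) pairs in file order; rejects empty files and
    duplicate identifiers (naming the offender)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: empty or not FASTA")
    seen = set()
    out = []
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate identifier {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, str(rec.seq)))
    return out


def read_mirnas(path: str | Path) -> list[MiRNA]:
    return [MiRNA(name=n, sequence=s) for n, s in read_fasta(path)]


def read_utrs(path: str | Path) -> list[UTRRegion]:
    return [UTRRegion(gene=n, sequence=s) for n, s in read_fasta(path)]


def _read_tsv(path: str | Path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.empty:
        raise ValueError(f"{path}: empty table")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        warnings.warn(f"{path}: ignoring extra column(s) {extra}")
    return df


def read_snp_table(path: str | Path) -> list[tuple[str, MiRSNP]]:
    """TSV with columns snp_id, gene, utr_position, ref, alt ->
    (gene, MiRSNP) pairs."""
    df = _read_tsv(path, ["snp_id", "gene", "utr_position", "ref", "alt"])
    out = []
    for i, row in df.iterrows():
        try:
            out.append(
                (
                    str(row["gene"]),
                    MiRSNP(str(row["snp_id"]), int(row["utr_position"]), str(row["ref"]), str(row["alt"])),
                )
            )
        except (ValueError, TypeError) as e:
            raise ValueError(f"{path} row {i + 2}: {e}") from e
    return out


def read_snps_vcf(path: str | Path) -> list[tuple[str, MiRSNP]]:
    """Minimal VCF reader: CHROM names the UTR (gene), POS is UTR-local
    1-based, REF/ALT single nucleotides; first ALT only."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            if not rec.alts:
                continue
            snp_id = rec.id or f"{rec.chrom}:{rec.pos}"
            out.append((rec.chrom, MiRSNP(snp_id, rec.pos, rec.ref, rec.alts[0])))
    if not out:
        raise ValueError(f"{path}: no usable variant records")
    return out


def read_genotype_table(path: str | Path) -> list[CohortGenotypes]:
    """TSV with columns cohort, n_CC, n_CT, n_TT."""
    df = _read_tsv(path, ["cohort", "n_CC", "n_CT", "n_TT"])
    if df["cohort"].duplicated().any():
        dup = df.loc[df["cohort"].duplicated(), "cohort"].iloc[0]
        raise ValueError(f"{path}: duplicate cohort label {dup!r}")
    out = []
    for i, row in df.iterrows():
        for col in ("n_CC", "n_CT", "n_TT"):
            v = row[col]
            if pd.isna(v) or float(v) != int(v) or int(v) < 0:
                raise ValueError(f"{path} row {i + 2}: {col}={v!r} is not a non-negative integer")
        out.append(
            CohortGenotypes(str(row["cohort"]), int(row["n_CC"]), int(row["n_CT"]), int(row["n_TT"]))
        )
    return out


def read_carrier_table(path: str | Path) -> dict[str, tuple[int, int]]:
    """Pre-collapsed carrier counts: TSV with columns group, carriers, total."""
    df = _read_tsv(path, ["group", "carriers", "total"])
    out = {}
    for i, row in df.iterrows():
        x, n = int(row["carriers"]), int(row["total"])
        if not 0 <= x <= n:
            raise ValueError(f"{path} row {i + 2}: carriers outside [0, total]")
        out[str(row["group"])] = (x, n)
    return out


def read_predictor_hits(path: str | Path) -> pd.DataFrame:
    """Predictor hit table: columns gene, mirna, source (one row per tool call)."""
    return _read_tsv(path, ["gene", "mirna", "source"])


def read_published_sites(path: str | Path) -> list[MRETarget]:
    """Load a consensus prediction table printed in the descending report
    convention (columns gene, mirna, seed_len, start, sequence, end, pvalue,
    sources).

    START pairs miRNA nucleotide 1, so ascending coordinates are
    ``utr_end = start`` and ``utr_start = start - seed_len + 1``.  The END
    column is redundant and occasionally typo-ridden in printed tables; it
    is ignored in favour of START + seed length.
    """
    df = _read_tsv(path, ["gene", "mirna", "seed_len", "start", "sequence", "end", "pvalue", "sources"])
    out = []
    for _, r in df.iterrows():
        k = int(r["seed_len"])
        end_asc = int(r["start"])
        out.append(
            MRETarget(
                gene=str(r["gene"]),
                mirna=str(r["mirna"]),
                utr_start=end_asc - k + 1,
                utr_end=end_asc,
                match_len=k,
                matched_prefix=str(r["sequence"]),
                pvalue=float(r["pvalue"]),
                sources=frozenset(str(r["sources"]).split(",")),
            )
        )
    return out


def read_enzyme_table(path: str | Path) -> dict[str, Enzyme]:
    df = _read_tsv(path, ["name", "pattern", "cut_top", "cut_bottom"])
    return {
        str(r["name"]): Enzyme(str(r["name"]), str(r["pattern"]), int(r["cut_top"]), int(r["cut_bottom"]))
        for _, r in df.iterrows()
    }


def _header_lines(seed, params: dict) -> list[str]:
    lines = [f"# mirsnpkit {__version__}"]
    if seed is not None:
        lines.append(f"# seed: {seed}")
    for k in sorted(params):
        lines.append(f"# {k}: {params[k]}")
    return lines


def write_mre_table(
    targets: list[MRETarget],
    path: str | Path,
    seed=None,
    **params,
) -> None:
    """TSV of predicted sites (ascending coordinates, plus the descending
    report convention some tools print)."""
    rows = [
        {
            "gene": t.gene,
            "mirna": t.mirna,
            "utr_start": t.utr_start,
            "utr_end": t.utr_end,
            "match_len": t.match_len,
            "matched_prefix": t.matched_prefix,
            "pvalue": "" if t.pvalue is None else f"{t.pvalue:.6g}",
            "sources": ",".join(sorted(t.sources)),
            "start_reported": t.start_reported,
            "end_reported": t.end_reported,
        }
        for t in targets
    ]
    df = pd.DataFrame(
        rows,
        columns=[
            "gene", "mirna", "utr_start", "utr_end", "match_len",
            "matched_prefix", "pvalue", "sources", "start_reported", "end_reported",
        ],
    )
    with open(path, "w") as fh:
        fh.write("\n".join(_header_lines(seed, params)) + "\n")
        df.to_csv(fh, sep="\t", index=False)


def write_bed6(targets: list[MRETarget], path: str | Path) -> None:
    """BED6, UTR-local: 0-based half-open conversion happens here and only here."""
    with open(path, "w") as fh:
        for t in targets:
            score = 0 if t.pvalue is None else min(1000, int(round(-100 * _log10(t.pvalue))))
            fh.write(
                f"{t.gene}\t{t.utr_start - 1}\t{t.utr_end}\t{t.mirna}\t{score}\t+\n"
            )


def _log10(p: float) -> float:
    import math

    return math.log10(p) if p > 0 else -30.0


def write_report(
    results: list[dict],
    path: str | Path,
    format: str = "tsv",
    seed=None,
    **params,
) -> None:
    """Write analysis results as TSV (one row per comparison, '#' header
    block) or JSON ({"meta": ..., "results": ...}).  Byte-identical across
    reruns with identical inputs and seed."""
    path = Path(path)
    if format == "json":
        payload = {
            "meta": {"package": "mirsnpkit", "version": __version__, "seed": seed, **params},
            "results": results,
        }
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    elif format == "tsv":
        df = pd.DataFrame(results)
        with open(path, "w") as fh:
            fh.write("\n".join(_header_lines(seed, params)) + "\n")
            df.to_csv(fh, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report(path: str | Path) -> list[dict]:
    """Parse either report format back into a list of row dicts."""
    path = Path(path)
    text = path.read_text()
    if text.lstrip().startswith("{"):
        return json.loads(text)["results"]
    df = pd.read_csv(path, sep="\t", comment="#")
    return df.to_dict(orient="records")
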