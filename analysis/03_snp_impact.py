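"""Classify the planted miRSNP on the synthetic UTR fixture.

The fixture reproduces the positional structure of the motivating variant:
a C>U change at the UTR base pairing seed nucleotide 2 of the miRNA, which
should abolish the site on the alternate allele.  Writes
results/snp_impact/impact.tsv.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mirsnpkit import classify_impact  # noqa: E402
from mirsnpkit import io  # noqa: E402

OUT = ROOT / "results" / "snp_impact"
OUT.mkdir(parents=True, exist_ok=True)
SIM = ROOT / "results" / "sim"


def main() -> None:
    if not (SIM / "snps.tsv").exists():
        sys.exit("run analysis/01_simulate_fixtures.py first")
    utr = io.read_utrs(SIM / "utr.fasta")[0]
    mirna = io.read_mirnas(SIM / "mirna.fasta")[0]
    rows = []
    for gene, snp in io.read_snp_table(SIM / "snps.tsv"):
        res = classify_impact(snp, mirna, utr, min_match=7)
        rows.append({
            "snp_id": snp.snp_id,
            "gene": gene,
            "mirna": res.mirna,
            "mirna_position": res.mirna_position,
            "in_seed": res.in_seed,
            "classification": res.classification.value,
        })
        print(f"{snp.snp_id}: pairs miRNA nt {res.mirna_position} "
              f"({'seed' if res.in_seed else 'non-seed'}), "
              f"classification = {res.classification.value}")
    io.write_report(rows, OUT / "impact.tsv", format="tsv", min_match=7)


if __name__ == "__main__":
    main()
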