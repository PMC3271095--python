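"""In-silico check of the engineered-mismatch RFLP genotyping assay.

The forward primer substitutes the penultimate template T by an A, so PCR
of the T allele — and only the T allele — completes a BsrI recognition site
(ACTGG on the bottom strand) in the amplicon.  The template here is a
synthetic flank around the published primer pair (the real genomic context
is not bundled); only the qualitative cut/no-cut contrast is meaningful.

Writes results/rflp/assay.json.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mirsnpkit import allele_discrimination, make_rflp_fixture  # noqa: E402
from mirsnpkit import io  # noqa: E402
from mirsnpkit.io import read_enzyme_table  # noqa: E402

OUT = ROOT / "results" / "rflp"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 20120202


def main() -> None:
    enzyme = read_enzyme_table(ROOT / "data" / "enzymes.tsv")["BsrI"]
    template, snp, fwd, rev = make_rflp_fixture(seed=SEED)
    ref_res, alt_res, discriminates = allele_discrimination(template, snp, fwd, rev, enzyme)
    rows = [
        {"allele": r.allele,
         "n_recognition_sites": len(r.site_positions),
         "fragment_lengths": list(r.fragment_lengths)}
        for r in (ref_res, alt_res)
    ] + [{"discriminates": discriminates}]
    io.write_report(rows, OUT / "assay.json", format="json", seed=SEED, enzyme=enzyme.name)
    for r in (ref_res, alt_res):
        state = "cut" if len(r.fragment_lengths) > 1 else "uncut"
        print(f"allele {r.allele}: {state}, fragments {list(r.fragment_lengths)}")
    print(f"alleles discriminated by fragment pattern: {discriminates}")


if __name__ == "__main__":
    main()
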