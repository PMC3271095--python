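"""Exact association statistics on the study genotype tables.

Runs the dominant-model (CT/TT carrier) comparisons on the two nephropathy
cohorts with Barnard's unconditional exact test (pooled-Wald ordering,
nuisance maximized on a 1e-4 grid), the per-sex carrier comparison, carrier
odds ratios, and the Hardy-Weinberg check on the control sample.  No
multiple-testing adjustment is applied.

Writes results/association/{comparisons.tsv,comparisons.json}.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from mirsnpkit import (  # noqa: E402
    ContingencyTable2x2,
    barnard_two_sided,
    carrier_comparison,
    hwe_chi2,
    odds_ratio,
)
from mirsnpkit import io  # noqa: E402

OUT = ROOT / "results" / "association"
OUT.mkdir(parents=True, exist_ok=True)
GRID = 1e-4

COMPARISONS = [
    ("mild_cfhr5", "severe_cfhr5"),
    ("mild_tbmn", "severe_tbmn"),
    ("mild_tbmn", "mild_cfhr5"),
    ("severe_tbmn", "severe_cfhr5"),
]


def main() -> None:
    cohorts = {c.label: c for c in io.read_genotype_table(ROOT / "data" / "cohort_genotype_counts.tsv")}
    rows = []
    for ref, case in COMPARISONS:
        r = carrier_comparison(cohorts[ref], cohorts[case], grid_step=GRID)
        rows.append(r)
        print(f"{ref} ({r['carriers1']}/{r['n1']}) vs {case} ({r['carriers2']}/{r['n2']}): "
              f"W = {r['wald']:+.3f}, two-sided p = {r['p_value']:.3f}, "
              f"carrier OR = {r['odds_ratio']:.2f}")

    women = io.read_carrier_table(ROOT / "data" / "cfhr5_women_carriers.tsv")
    (x1, n1), (x2, n2) = women["mild_women"], women["severe_women"]
    t = ContingencyTable2x2("mild_women", "severe_women", x1, n1, x2, n2)
    res = barnard_two_sided(t, grid_step=GRID)
    orw = odds_ratio(t)
    rows.append({
        "group1": "mild_women", "group2": "severe_women",
        "carriers1": x1, "n1": n1, "carriers2": x2, "n2": n2,
        "wald": res.W_obs, "p_value": res.p_two_sided, "pi_star": res.pi_star,
        "odds_ratio": orw, "alternative": res.alternative,
    })
    print(f"mild_women ({x1}/{n1}) vs severe_women ({x2}/{n2}): "
          f"W = {res.W_obs:+.3f}, two-sided p = {res.p_two_sided:.3f}, carrier OR = {orw:.1f}")

    controls = io.read_genotype_table(ROOT / "data" / "control_genotype_counts.tsv")[0]
    hwe = hwe_chi2(controls)
    print(f"controls ({controls.n_CC}/{controls.n_CT}/{controls.n_TT}, counts reconstructed "
          f"from rounded percentages): HWE chi2 = {hwe.chi2:.3f}, p = {hwe.p:.3f} "
          f"({'consistent with' if hwe.p > 0.05 else 'deviates from'} HWE)")
    rows.append({"group1": "controls", "group2": "", "wald": "", "p_value": hwe.p,
                 "odds_ratio": "", "pi_star": "", "alternative": "HWE chi-square",
                 "carriers1": "", "n1": controls.total, "carriers2": "", "n2": ""})

    io.write_report(rows, OUT / "comparisons.tsv", format="tsv", grid_step=GRID, model="dominant")
    io.write_report(rows, OUT / "comparisons.json", format="json", grid_step=GRID, model="dominant")


if __name__ == "__main__":
    main()
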