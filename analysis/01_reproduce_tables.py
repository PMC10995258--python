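#!/usr/bin/env python
"""Recompute the published per-allele association tables from carrier counts.

Every statistic (odds ratio, Woolf 95% CI, Wald and Fisher p, per-locus
Bonferroni Pc) is recomputed from the shipped carrier-count fixtures for
the 56-case / 192-control cohort and compared with the printed values.

Finding: all comparable rows reproduce at printed precision; the printed
p-values are the two-sided Wald test on ln(OR) (e.g. A*26:01:01 p=0.028),
not the Fisher exact test the table captions name (Fisher gives 0.049).
"""

from pathlib import Path

from bdhla.association import trunc3
from bdhla.fixtures import HIGHLIGHTED, fixture_results, load_fixture, reproduce_tables

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

fixture = load_fixture("both")
report = reproduce_tables(fixture)
report.to_csv(OUT / "table_reproduction.tsv", sep="\t", index=False)

comparable = report[report.match_or != ""]
matched = (comparable.match_or & comparable.match_p & comparable.match_ci).sum()
print(f"{len(report)} published rows; {matched}/{len(comparable)} comparable rows "
      "reproduce printed OR/p/CI at printed precision")

print("\nhighlighted alleles (recomputed):")
results = {str(r.allele): r for r in fixture_results(fixture)}
for allele in HIGHLIGHTED:
    r = results[allele]
    print(f"  {allele:15s} OR {trunc3(r.or_):.3f}  p_wald {r.p_wald:.3f}  "
          f"p_fisher {r.p_fisher:.3f}  Pc {r.pc:.3f} (m={r.m})")
print(f"\nwrote {OUT / 'table_reproduction.tsv'}")
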