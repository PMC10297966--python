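"""Compare per-arm readouts between cell lines with Welch t-tests.

Simulates three lines, tabulates per-arm fusion/ITS+ percentages and
per-arm CVs, and tests every pair of lines for differences (two-tailed,
unequal variances) — the same per-arm comparison used to distinguish
ALT+ subtypes.
"""

from telomap import compare_cell_lines, make_reference, profile_from_table1, simulate_and_analyze

reference = make_reference(seed=1)
tables = {}
for name in ("U2OS", "SK-MEL-2", "LNCaP"):
    result = simulate_and_analyze(profile_from_table1(name), reference, seed=7)
    tables[name] = result.arm_tables

for metric in ("its_plus_pct_by_arm", "cv_by_arm"):
    print(f"\n{metric}:")
    results = compare_cell_lines(tables, metric)
    names = list(tables)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            r = results[(a, b)]
            if r is None:
                print(f"  {a:9s} vs {b:9s}  insufficient shared arms")
            else:
                print(f"  {a:9s} vs {b:9s}  t = {r.t_statistic:7.2f}  "
                      f"df = {r.degrees_of_freedom:5.1f}  p = {r.p_value_two_tailed:.2e}")

print("""
Small p-values for ITS+ percentage separate the fusion-rich ALT+ lines from
the TEL+ line (and the two ALT+ lines from each other); per-arm CV likewise
reflects the greater telomere-length heterogeneity of ALT+ cells.""")
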