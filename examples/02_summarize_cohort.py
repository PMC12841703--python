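"""Descriptive summary of a cohort, stratified by procedure outcome.

Counts and per-column percentages for each of the eight predictors, the
convention used in clinical baseline tables.
"""

from preecv import summarize_cohort, published_cohort_fixture

summary = summarize_cohort(published_cohort_fixture())
print(f"N = {summary.n_total}: {summary.n_success} successful versions "
      f"({100 * summary.success_rate:.1f}%), {summary.n_failure} failures\n")

print(f"{'predictor':<22}{'level':<18}{'all':>12}{'success':>14}{'failure':>14}")
for predictor, levels in summary.table.items():
    for level, cols in levels.items():
        cells = [f"{cols[c].count} ({cols[c].percent}%)" for c in ("all", "success", "failure")]
        print(f"{predictor:<22}{level:<18}{cells[0]:>12}{cells[1]:>14}{cells[2]:>14}")

print("\nEach cell is count (percent of its own column); e.g. the failure "
      "column shows how common each factor is among failed attempts.")
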