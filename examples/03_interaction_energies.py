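"""Work with ensemble-docking interaction energies (IEs).

Parses a docking-engine output for the best pose score, builds complete
seven-conformation IE profiles with the mock scorer, re-derives the
quantile screening threshold from "inhibitor" profiles, and applies the
strict per-conformation filter.
"""

from cypscreen import (
    default_job_spec,
    fixture_records,
    ie_pass_filter,
    ie_threshold_from_inhibitors,
    mock_ie_profiles,
    parse_docking_output,
)

spec = default_job_spec("1R9O")
print(f"grid for {spec.receptor}: center {spec.grid_center}, box {spec.box_size} A, "
      f"exhaustiveness {spec.exhaustiveness}, {spec.max_modes} modes")

log = """REMARK VINA RESULT:    -8.7   0.000   0.000
REMARK VINA RESULT:    -9.1   1.822   2.310
REMARK VINA RESULT:    -7.2   3.401   5.114"""
print(f"best score from 3-mode docking log: {parse_docking_output(log)} kcal/mol")

records = fixture_records(druglike_only=True)
profiles = mock_ie_profiles(records, seed=2022)
threshold = ie_threshold_from_inhibitors(profiles, q=0.75)
passing = [p.molecule_id for p in profiles if ie_pass_filter(p, threshold)]
print(f"75%-quantile threshold over {len(profiles)} x 7 pooled scores: "
      f"{threshold:.2f} kcal/mol")
print(f"{len(passing)} / {len(profiles)} molecules below threshold in ALL "
      f"seven conformations: {passing}")
# The filter is strict (<) and per-conformation: one weak conformation
# disqualifies a molecule even if the other six scores are strong.
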