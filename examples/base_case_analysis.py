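"""Run the full base-case cost-utility analysis.

Simulates both care strategies over a 12-month horizon for a fresh cohort at
every starting age 65-90, then classifies the summary ICER against the
15,000 EUR/QALY willingness-to-pay threshold.
"""

from demcare_cua import run_base_case

bundle = run_base_case(out_dir="scratch/base_case")
by_age = bundle["incremental_by_age"]
s = bundle["summary"]

print(by_age.head(3).to_string(index=False))
print("...")
print(by_age.tail(3).to_string(index=False))
print()
print(f"mean delta cost   = {s.delta_cost:9.2f} EUR   (negative: the review saves money)")
print(f"mean delta effect = {s.delta_effect:9.5f} QALY  (positive: patients live longer)")
print(f"ICER class        = {s.icer_class}  (cheaper AND more effective)")
print(f"NMB at 15,000 EUR/QALY = {s.nmb:.2f} EUR  -> accepted = {s.accepted}")
# A dominant classification means the deprescribing review is preferred at
# any willingness-to-pay threshold, including the lowest one considered.
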