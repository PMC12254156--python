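"""Inspect the per-person activity-cost curves.

Pursuing a more ambitious organisational target is disproportionately
expensive: unit cost follows a normalised exponential in the target, and
retention support mirrors it (a low disengagement target is the costly end).
"""

from reaimsim import unit_cost_increasing, unit_cost_retention

print("target   reach-type cost   retention cost (at that disengagement)")
for theta in (0.0, 0.25, 0.5, 0.75, 0.94, 1.0):
    print(f"{theta:5.2f}    {unit_cost_increasing(theta):15.5f}   "
          f"{unit_cost_retention(theta):15.5f}")

print()
print("Both curves are normalised to [0, base_cost] (default base 1, steepness")
print("k=3): a reach-type activity costs nothing at target 0 and the full base")
print("cost per person at target 1, convex in between; retention support costs")
print("the most when the tolerated disengagement is lowest.")
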