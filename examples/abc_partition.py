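"""Partition a small importance vector into ABC subsets.

Builds a right-skewed vector of 20 item values, computes the ABC curve
and its two boundaries, and prints the membership.  The Juran point is
the curve point closest to the ideal Pareto point (0, 1) and marks the
A|B boundary; the break-even point (curve slope = 1) marks B|C.
"""

import numpy as np

from cabc import ItemSet, partition

rng = np.random.default_rng(42)
values = np.sort(rng.lognormal(0.0, 1.5, 20))[::-1]
items = ItemSet([f"marker{i + 1:02d}" for i in range(20)], values)

part = partition(items)

print(f"Juran (A|B) point: x = {part.juran[0]:.3f}, y = {part.juran[1]:.3f}")
print(f"break-even (B|C) point: x = {part.break_even[0]:.3f}, "
      f"y = {part.break_even[1]:.3f}")
print(f"A ({len(part.set_a)} items): {', '.join(part.set_a)}")
print(f"B ({len(part.set_b)} items): {', '.join(part.set_b)}")
print(f"C ({len(part.set_c)} items): {', '.join(part.set_c)}")
print(f"subset A holds {100 * part.a_fraction:.0f}% of the items but "
      f"{100 * part.juran[1]:.0f}% of the total value")
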