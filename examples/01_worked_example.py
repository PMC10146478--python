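"""The virtual-controls probability model at the published worked example.

A treated student was 127 months old at pretest with a psych score of 8.97;
her pegged normative percentile carries psych scores 8.93 at 129 months
(posttest) and 8.73 at 137 months (follow-up).  With the published alcohol
weights, the model turns each (psych, age) pair into an expected
probability of past-30-day drinking for the virtual control case.
"""

from virtualcontrols.calibration import probability_of_use
from virtualcontrols.data import load_reference_weights

weights = load_reference_weights()["alcohol"]
print(f"alcohol weights: intercept={weights.b_intercept}, "
      f"psych={weights.b_psych}, psych*age={weights.b_psych_age}")

for wave, psych, age in [("pretest", 8.97, 127),
                         ("posttest", 8.93, 129),
                         ("follow-up", 8.73, 137)]:
    p = probability_of_use(weights, psych, age)
    print(f"{wave:10s} psych={psych:.2f} age={age} mo -> "
          f"P(30-day alcohol use) = {100 * p:.2f}%")

# The three percentages are the virtual control's expected drinking risk at
# each wave: risk roughly quadruples between pretest and follow-up even
# though the pegged percentile never changes, because normative psych
# scores decline with age.
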