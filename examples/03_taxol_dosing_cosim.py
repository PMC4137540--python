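"""Find a Taxol schedule that clears the tumor without poisoning the liver.

Couples the toy hepatic pharmacokinetic ODE model (saturable Taxol
metabolism producing lactate) to an agent-based tumor population (one
deregulated clone inside a homeostatic wild-type population) through a
shared plasma Taxol pool.  The drug kills any cell that attempts to divide
while Taxol is present.  Scanning (dose, interval) schedules exhibits all
the qualitative outcome classes, including the optimal one: tumor cleared,
lactate always below the toxicity threshold.
"""

import numpy as np

from crossscale.cosim import (
    AgentPopulationModel, CompositeModel, classify_outcome, cosimulate,
)
from crossscale.zoo import make_liver_model

liver = make_liver_model()
t_end = 600.0

print(f"{'dose':>6} {'interval':>9} {'outcome':<32} {'mutants':>8} {'peak Lac':>9}")
for dose, interval in [(0.0, np.inf), (0.5, 200.0), (4.0, 40.0),
                       (4.0, 20.0), (10.0, 20.0)]:
    schedule = ([(t, dose) for t in np.arange(20.0, t_end, interval)]
                if dose > 0 else [])
    composite = CompositeModel(
        population=AgentPopulationModel(), liver=liver,
        dosing_schedule=schedule,
    )
    trace = cosimulate(composite, t_end, seed=3)
    out = classify_outcome(trace)
    worst = max(abs(i) for _, _, i in trace.shared_history)
    print(f"{dose:>6} {interval:>9} {out.label:<32} "
          f"{out.final_mutant_count:>8} {out.peak_lactate:>9.2f}")

# Outcome labels: the tumor is "cleared" when the mutant lineage is
# extinguished by t_end, and the liver is "toxic" when peak lactate exceeds
# the declared threshold (8).  Moderate doses at a ~50% duty cycle clear the
# tumor while lactate stays below threshold; dense or heavy dosing clears it
# at the cost of toxicity; token dosing leaves the tumor.
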