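"""Reproduce the worked Markov adjustment of the 2004 forecast.

Builds the ratio path (actual / amended prediction) for 1991-2003 from
the published amended column, assigns each year to one of the four
ratio bands, estimates the one-step transition matrix, predicts 2004's
state from 2003's, and adjusts the 2004 base prediction by the
predicted band's midpoint ratio.
"""

import numpy as np

import greymarkov as gm
from greymarkov import casestudy
from greymarkov.markov import transition_model

series = casestudy.actual_series()
space = casestudy.state_space()

years = list(range(1991, 2004))
ratios = np.array([series.value_at(y) / casestudy.PUBLISHED_AMENDED[y]
                   for y in years])
path = gm.assign_states(ratios, space)
print("state path 1991-2003:",
      " ".join(f"E{s}" for s in path.states))

model = transition_model(path, step=1)
print("\none-step transition counts (rows = from-state):")
print(model.counts)

current = path.states[-1]
predicted = gm.predict_state([model], current)
print(f"\n2003 is in E{current}; argmax of row {current} predicts "
      f"E{predicted} for 2004")

base = casestudy.PUBLISHED_AMENDED[2004]
adj = gm.adjust_forecast(base, predicted, space)
lo, hi = adj.interval
print(f"band [{lo:.2f}, {hi:.2f}] -> midpoint ratio {adj.adjusted_ratio}")
print(f"adjusted 2004 forecast = {base} x {adj.adjusted_ratio} "
      f"= {adj.adjusted_value:.1f} ~ {adj.rounded} deaths "
      f"(actual: {casestudy.COMPARISON_2004_2013[2004][0]})")
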