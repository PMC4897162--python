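"""Fit the grey exponential-trend model to the packaged case study.

Loads the 1990-2010 Chinese coal-mine accident death series, estimates
the SCGM(1,1)_c parameters and prints the restored fit next to the
actual values.  The development coefficient a is the per-year log-ratio
of the trend (negative = declining toll); the restored prediction for
year k is 2*M*exp(a*k) under the published-table exponent convention.
"""

import greymarkov as gm

series = gm.load_fixture("china_coal_1990_2010")
params = gm.fit(series)
print(f"development coefficient a = {params.a:.6f}  "
      f"(yearly trend factor e^a = {2.718281828**params.a:.4f})")
print(f"amplitude b = {params.b:.1f},  restored amplitude M = {params.M:.1f}")
print()

ks = range(2, series.n + 1)
fitted = gm.restored_fit(params, ks, shift=1)
diag = gm.diagnostics(series, fitted)
print("year  actual  fitted  ratio%")
for k, f in zip(ks, fitted):
    year = series.label_for_index(k)
    actual = series.value_at(year)
    print(f"{year}  {actual:6.0f}  {f:6.0f}  {100 * actual / f:5.0f}")
print()
print("The fitted column declines smoothly at e^a per year; the ratio")
print("column (actual/fitted) is the fluctuation the Markov layer models.")
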