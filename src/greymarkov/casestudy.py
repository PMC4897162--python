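"""Published case-study inputs: Chinese coal-mine accident deaths.

The package's worked case study is the 1990-2010 national coal-mine
accident death toll together with the values the original study
published alongside it: its grey fit, residual-amended fit, the
four ratio-band states, the residual-model parameters it reports, and
its 2004-2013 out-of-sample comparison (whose actual column extends to
2013).  These are *inputs* for reproduction and cross-checking; all
package computations derive their own numbers from the raw series.

Known inconsistencies of the published tables (documented in
docs/methods.md): the published development pair (a, b) cannot
regenerate the published fitted column, whereas refitting the raw
series and evaluating with the published exponent convention does; the
1996 amended row and ratio entry are not reproducible from any of the
published numbers; the 2010 fitted value 3987 is a suspected misprint
of ~3973; and the printed percent ratios for 1996, 1998-2002 and 2008
disagree with their own actual/amended quotients.
"""

from __future__ import annotations

from .markov import StateSpace
from .series import TimeSeries, load_fixture

FIXTURE_NAME = "china_coal_1990_2010"

#: Development pair printed for the main model (not reproducible from
#: the raw data; kept for reference only).
PUBLISHED_A = -0.039436
PUBLISHED_B = -236878.0

#: First-layer residual model parameters as published; under the
#: ``2*M1*exp(a1*k)`` convention these reproduce the amended column.
PUBLISHED_RESIDUAL_A1 = -0.0632
PUBLISHED_RESIDUAL_B1 = -21827.6

#: Published grey fitted values, 1991-2010 (k = 2..21).
PUBLISHED_GREY_FIT = {
    1991: 7716, 1992: 7451, 1993: 7196, 1994: 6949, 1995: 6710,
    1996: 6479, 1997: 6257, 1998: 6042, 1999: 5835, 2000: 5635,
    2001: 5441, 2002: 5254, 2003: 5074, 2004: 4899, 2005: 4731,
    2006: 4569, 2007: 4412, 2008: 4261, 2009: 4114, 2010: 3987,
}

#: Published residual-amended fitted values, 1991-2010.
PUBLISHED_AMENDED = {
    1991: 6501, 1992: 6310, 1993: 6125, 1994: 5944, 1995: 5766,
    1996: 5565, 1997: 5425, 1998: 6823, 1999: 6568, 2000: 6323,
    2001: 6087, 2002: 5860, 2003: 5643, 2004: 5433, 2005: 5233,
    2006: 5040, 2007: 3970, 2008: 3846, 2009: 3725, 2010: 3592,
}

#: Published whole-percent ratio column (actual / amended), 1991-2010.
PUBLISHED_RATIO_PERCENT = {
    1991: 96, 1992: 93, 1993: 84, 1994: 111, 1995: 108,
    1996: 88, 1997: 113, 1998: 93, 1999: 119, 2000: 118,
    2001: 111, 2002: 114, 2003: 119, 2004: 111, 2005: 114,
    2006: 94, 2007: 95, 2008: 69, 2009: 71, 2010: 68,
}

#: Ratio-band state division (four states, fractions).
STATE_BOUNDARIES = (0.60, 0.75, 0.90, 1.05, 1.20)
STATE_DESCRIPTIONS = (
    "strong decreasing year",
    "poor decreasing year",
    "poor increasing year",
    "strong increasing year",
)

#: 2004-2013 comparison: actual deaths, amended-model prediction and
#: relative error, Markov-adjusted prediction and relative error.
COMPARISON_2004_2013 = {
    2004: (6027, 5433, 0.099, 6112, 0.014),
    2005: (5986, 5233, 0.126, 5887, 0.017),
    2006: (4746, 5040, 0.062, 4914, 0.035),
    2007: (3786, 3970, 0.049, 3870, 0.022),
    2008: (2631, 3846, 0.462, 3749, 0.425),
    2009: (2631, 3725, 0.416, 2328, 0.115),
    2010: (2433, 3592, 0.476, 2424, 0.004),
    2011: (1973, 3357, 0.701, 2265, 0.147),
    2012: (1384, 2142, 0.548, 1446, 0.045),
    2013: (1067, 1934, 0.813, 1305, 0.223),
}


def actual_series() -> TimeSeries:
    """The raw 1990-2010 death-toll series (packaged fixture)."""
    return load_fixture(FIXTURE_NAME)


def state_space() -> StateSpace:
    """The published four-band state space on the ratio scale."""
    return StateSpace(STATE_BOUNDARIES)


def actual_deaths_2004_2013() -> list[float]:
    """Actual deaths 2004-2013 (the decline-rate window)."""
    return [float(COMPARISON_2004_2013[y][0]) for y in range(2004, 2014)]
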