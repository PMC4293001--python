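"""Embedded teaching fixture.

The 11 observations of the acute myelogenous leukemia (AML) trial's
"maintained" arm — the canonical public dataset shipped with the R survival
package — small enough to reason through by hand: 7 distinct event times,
one censoring tied just after the second event ("13+"), two censorings
strictly between events, and one long trailing censored observation.
"""

from __future__ import annotations

AML_MAINTAINED_TIMES = (9, 13, 13, 18, 23, 28, 31, 34, 45, 48, 161)
AML_MAINTAINED_STATUS = (1, 1, 0, 1, 1, 0, 1, 1, 0, 1, 0)


def load_aml_maintained() -> list[tuple[float, int]]:
    """(time, status) records; status 1 = event, 0 = censored."""
    return list(zip(AML_MAINTAINED_TIMES, AML_MAINTAINED_STATUS))
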