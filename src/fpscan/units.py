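"""Unit conventions and conversions used throughout the package.

Internal conventions:

* distances  : micrometres (um)
* time       : nanoseconds (ns)
* pressure   : kilopascals (kPa)
* frequency  : megahertz (MHz) at API surfaces, rad/ns internally
* sound speed: metres per second (m/s) at API surfaces

With these choices a sound speed of 1500 m/s is 1.5 um/ns, and a 1 MHz
frequency corresponds to a 1000 ns period, so all quantities stay O(1)
in double precision.
"""

#: multiply m/s by this to get um/ns
MPS_TO_UM_PER_NS = 1e-3

#: multiply MHz by this to get cycles/ns
MHZ_TO_PER_NS = 1e-3

#: multiply um by this to get metres
UM_TO_M = 1e-6

#: multiply mm by this to get um
MM_TO_UM = 1e3


def c_um_per_ns(c_m_per_s: float) -> float:
    """Convert a sound speed in m/s to um/ns."""
    return c_m_per_s * MPS_TO_UM_PER_NS


def f_per_ns(f_mhz: float) -> float:
    """Convert a frequency in MHz to cycles/ns."""
    return f_mhz * MHZ_TO_PER_NS
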