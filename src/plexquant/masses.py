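"""Theoretical m/z values of the TMT 10-plex reporter ions.

The reporter fragment released on HCD fragmentation of a TMT-labelled peptide
is the N-methyl-piperidine-derived immonium-type cation C8H16N+.  The ten
channels of the 10-plex kit share this skeleton and differ only in where the
heavy isotopes sit: channels are offset by combinations of 13C (+1.003355 u)
and 15N (+0.997035 u) substitutions, which is why the N/C pairs (127N/127C,
128N/128C, ...) are only ~6.32 mDa apart and need the narrow extraction
window used downstream.

The m/z values are computed here from the elemental isotope compositions
(monoisotopic atomic masses via :mod:`pyteomics.mass`, minus one electron for
the cation) rather than copied from a table.
"""

from __future__ import annotations

from pyteomics import mass as _mass

#: Mass of the electron in unified atomic mass units (CODATA).
ELECTRON_MASS = 0.000548579909065

#: Ordered channel labels of the TMT 10-plex kit.
TMT10_CHANNELS = (
    "126", "127N", "127C", "128N", "128C",
    "129N", "129C", "130N", "130C", "131",
)

# (number of 13C, number of 15N) substitutions in the C8H16N reporter skeleton.
_SUBSTITUTIONS = {
    "126": (0, 0),
    "127N": (0, 1),
    "127C": (1, 0),
    "128N": (1, 1),
    "128C": (2, 0),
    "129N": (2, 1),
    "129C": (3, 0),
    "130N": (3, 1),
    "130C": (4, 0),
    "131": (4, 1),
}


def reporter_ion_mz(channel: str) -> float:
    """Monoisotopic m/z of the singly charged reporter cation for *channel*."""
    try:
        n_c13, n_n15 = _SUBSTITUTIONS[channel]
    except KeyError:
        raise ValueError(f"unknown TMT 10-plex channel: {channel!r}") from None
    formula = f"C[13]{n_c13}C{8 - n_c13}H16"
    formula += "N[15]1" if n_n15 else "N1"
    neutral = _mass.calculate_mass(composition=_mass.Composition(formula=formula))
    return neutral - ELECTRON_MASS


#: Theoretical reporter m/z values in channel order (strictly increasing).
TMT10_REPORTER_MZ = tuple(reporter_ion_mz(c) for c in TMT10_CHANNELS)
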