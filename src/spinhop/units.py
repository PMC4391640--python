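"""Unit conversions pinned in one place.

Internally everything is in Hartree atomic units (hartree, bohr, electron
mass, ħ = 1, atomic time unit).  User-facing boundaries use eV, fs, cm⁻¹
and Å.  All conversion factors derive from scipy's CODATA table so the
package never carries hand-typed constants.
"""

from __future__ import annotations

from scipy.constants import physical_constants as _pc

#: hartree -> eV
HARTREE_TO_EV: float = _pc["hartree-electron volt relationship"][0]
EV_TO_HARTREE: float = 1.0 / HARTREE_TO_EV

#: hartree -> cm^-1 (wavenumber of a photon with that energy)
HARTREE_TO_CM1: float = _pc["hartree-inverse meter relationship"][0] / 100.0
CM1_TO_HARTREE: float = 1.0 / HARTREE_TO_CM1

#: atomic time unit -> fs
AU_TIME_TO_FS: float = _pc["atomic unit of time"][0] * 1e15
FS_TO_AU_TIME: float = 1.0 / AU_TIME_TO_FS

#: bohr -> Å
BOHR_TO_ANGSTROM: float = _pc["Bohr radius"][0] * 1e10
ANGSTROM_TO_BOHR: float = 1.0 / BOHR_TO_ANGSTROM

#: unified atomic mass unit -> electron masses
AMU_TO_ME: float = _pc["atomic mass constant"][0] / _pc["electron mass"][0]
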