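"""Unit conversion constants.

Public interfaces use femtoseconds and electronvolts; the dynamics
propagators work in Hartree atomic units. The constants below are fixed
package-wide so that conversions are bit-reproducible.
"""

#: 1 atomic unit of time in femtoseconds
FS_PER_AUT = 0.02418884

#: 1 Hartree in electronvolts
EV_PER_HARTREE = 27.21139

#: hbar in eV fs
HBAR_EV_FS = 0.6582119569

#: atomic unit of intensity in W/cm^2 (E0 = 1 a.u. <-> I = this)
AU_INTENSITY_W_CM2 = 3.50945e16


def ev_to_au(x):
    return x / EV_PER_HARTREE


def au_to_ev(x):
    return x * EV_PER_HARTREE


def fs_to_au(x):
    return x / FS_PER_AUT


def au_to_fs(x):
    return x * FS_PER_AUT
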