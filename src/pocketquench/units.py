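"""Unit conversion constants (charges in e, lengths in Angstrom)."""

#: Coulomb energy prefactor: e^2/(4 pi eps0) in eV * Angstrom.
COULOMB_EV_ANGSTROM = 14.3996

#: 1 eV in wavenumbers.
EV_TO_INVCM = 8065.544

#: 1 e * Angstrom in Debye.
EANGSTROM_TO_DEBYE = 4.80321
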