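"""Packaged fixture tables for the α-synuclein modelling workflow.

All tables here are *synthetic* stand-ins generated by
:mod:`cldmd.synthetic` around the real 140-residue α-synuclein sequence
placed on a seeded claw-like compact trace (see ``make_fixtures.py`` note
in each file header).  They reproduce the shape and bookkeeping of the
experimental supplements this pipeline consumes — 30 short-range
crosslinks across ABAS/SDA/TATA/EDC, a CBDPS long-distance table, a
surface-modification ratio table and a per-residue deuteration profile —
but the numbers are simulated, not measured.
"""

from importlib import resources


def _path(name: str):
    return resources.files(__package__) / name


def crosslinks_short_path():
    """CSV with 30 short-range constraint crosslinks (synthetic)."""
    return _path("xl_short_synthetic.csv")


def crosslinks_cbdps_path():
    """CSV with long-distance CBDPS validation crosslinks (synthetic)."""
    return _path("xl_cbdps_synthetic.csv")


def sm_table_path():
    """CSV with surface-modification heavy/light ratios (synthetic)."""
    return _path("sm_synthetic.csv")


def hdx_table_path():
    """CSV with per-residue deuteration fractions (synthetic)."""
    return _path("hdx_synthetic.csv")
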