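"""Optional coordinate-file adapter: GRO/PDB → phosphorus z-table.

Delegates parsing to MDAnalysis, which reports positions in Å for every
format (converting from GRO's native nm itself); the single ÷10 here is
therefore the only unit handling this module does.  Inputs are assumed to
be already unwrapped along z.
"""

from __future__ import annotations

import pandas as pd

DEFAULT_SELECTION = "name P P8 P31 P*"


def coordinates_to_z_table(
    paths, atom_selection: str = DEFAULT_SELECTION
) -> pd.DataFrame:
    """Extract per-frame phosphorus z coordinates (nm) from GRO/PDB files.

    ``paths`` is one path or a sequence of paths, each one frame (or a
    multi-frame PDB); ``atom_selection`` is an MDAnalysis selection string,
    defaulting to common phosphate phosphorus atom names.
    """
    import MDAnalysis as mda

    if isinstance(paths, (str, bytes)) or not hasattr(paths, "__iter__"):
        paths = [paths]
    frames = []
    n_expected = None
    frame_counter = 0
    for path in paths:
        universe = mda.Universe(str(path))
        selection = universe.select_atoms(atom_selection)
        if len(selection) == 0:
            raise ValueError(
                f"{path}: selection {atom_selection!r} matched no atoms"
            )
        if n_expected is None:
            n_expected = len(selection)
        elif len(selection) != n_expected:
            raise ValueError(
                f"{path}: {len(selection)} selected atoms, expected {n_expected}"
            )
        for _ in universe.trajectory:
            frames.append(
                pd.DataFrame(
                    {
                        "frame": frame_counter,
                        "atom_index": range(len(selection)),
                        "z_nm": selection.positions[:, 2] / 10.0,  # Å → nm
                    }
                )
            )
            frame_counter += 1
    return pd.concat(frames, ignore_index=True)
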