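#!/usr/bin/env python
"""Regenerate the checked-in fixture files under fixtures/.

The files are a convenience export of the programmatic generators in
alchemap.fixtures (the tests build everything in memory and do not read
these files).
"""

from pathlib import Path

from alchemap.fixtures import FixtureSpec, make_congeneric_series
from alchemap.io import write_sdf, write_smiles_file


def main() -> None:
    out = Path(__file__).resolve().parent.parent / "fixtures"
    out.mkdir(exist_ok=True)
    series = make_congeneric_series(FixtureSpec())
    write_smiles_file(series, out / "toy_series.smi")
    write_sdf(series, out / "toy_series.sdf")
    close = make_congeneric_series(
        FixtureSpec(substituents=("C", "O", "Cl"), include_distant=False)
    )
    write_smiles_file(close, out / "close_series.smi")
    print(f"wrote fixtures to {out}")


if __name__ == "__main__":
    main()
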