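Place PDB entries here to enable the crystal-structure checks and the
crystal-derived quantities in `scripts/acceptance.py`:

    curl -O https://files.rcsb.org/download/4MMX.pdb
    curl -O https://files.rcsb.org/download/4MMZ.pdb
    curl -O https://files.rcsb.org/download/1JV2.pdb

The files are not redistributed with the package.
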