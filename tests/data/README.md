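# Optional real-data inputs

This directory holds optional real structure files that are not bundled
with the package. To enable the human-serum-albumin check (Tyr161 OH to
heme-Fe distance), download PDB entry 1N5U here:

    wget -O tests/data/1n5u.pdb https://files.rcsb.org/download/1N5U.pdb

`tests/test_acceptance.py` and `scripts/acceptance.py` pick it up
automatically.
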