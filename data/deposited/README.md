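# Deposited records (optional)

Place GenBank flat files for the published replicons here, named
`<accession>.gb` (e.g. `NC_014115.gb` for pTN2, `NC_014110.gb` for
pP12-1, `NC_013408.gb` for pMETVU01), to enable the exact
statistics-parity checks in `tests/test_acceptance.py`. The files are
not distributed with the package; download them from GenBank. Everything
else in the test suite runs without them.
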