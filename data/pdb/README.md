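# Deposited structures (user-supplied)

Place PDB entries here as `<id>.pdb` (lower-case id) to enable the
structure-based comparisons and the `test_paper_*` acceptance tests:

```bash
for id in 6mi3 6mi4 3brv 4dmd; do
    curl -o $id.pdb https://files.rcsb.org/download/${id^^}.pdb
done
```

These files are not redistributed with the package.
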