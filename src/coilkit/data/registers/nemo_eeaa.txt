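# Heptad register of the coiled-coil-stabilized NEMO IKKbeta-binding-domain
# construct (construct numbering 23-139): regular repeats with a four-residue
# stutter insert (abcd) at 79-82.  Reconstructed from the published a/a'/d
# table columns; letters within the irregular heptad 72-78 beyond its a/d
# anchors are assumed cyclic.
23-78:a..g;79-82:abcd;83-139:a..g
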