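# Donor/acceptor chemistry for geometric hydrogen-bond detection.
# Element-based typing: N/O heavy atoms with an attached hydrogen donate,
# N/O heavy atoms accept.  Richer per-atom typing (as in dedicated H-bond
# programs) is intentionally not reproduced; the two criteria presets are
# purely geometric threshold sets.
donor_elements: [N, O]
acceptor_elements: [N, O]
max_hydrogen_bond_length: 1.25   # Angstrom, covalent H attachment cutoff
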