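>R1_synthetic motif-constrained synthetic repeat (Ser-X5-Gln-X-Gly-X-Gly-Asn-X-Ala-X3-Gln-X); user-replaceable default, not an experimental sequence
SSTENDQGGKGNAAMYYQN
>R2_synthetic motif-constrained synthetic repeat (Ser-X5-Gln-X-Gly-X-Gly-Asn-X-Ala-X3-Gln-X); user-replaceable default, not an experimental sequence
SHYQIEQSGIGNNANHIQVS
>R3_synthetic motif-constrained synthetic repeat (Ser-X5-Gln-X-Gly-X-Gly-Asn-X-Ala-X3-Gln-X); user-replaceable default, not an experimental sequence
SKEMMGQTGGGNHADQNQKHV
>R4_synthetic motif-constrained synthetic repeat (Ser-X5-Gln-X-Gly-X-Gly-Asn-X-Ala-X3-Gln-X); user-replaceable default, not an experimental sequence
SMHDFRQFGMGNTALTHQD
>R5_synthetic motif-constrained synthetic repeat (Ser-X5-Gln-X-Gly-X-Gly-Asn-X-Ala-X3-Gln-X); user-replaceable default, not an experimental sequence
SQTHQGQFGFGNEAQIFQRH
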