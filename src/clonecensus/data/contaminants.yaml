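# Default contaminant blocklist: taxa removed before community analysis.
# Apicomplexa reads commonly arise from cross-annotation of a water
# contaminant (Bradyrhizobium) against flawed reference assemblies; the
# phages and viruses below are recurrent reagent contaminants of
# whole-genome-amplification and library kits.
blocklist:
  - Apicomplexa
  - Enterobacteria phage M13
  - Enterobacteria phage T7
  - Enterobacteria phage phiX-174
  - Bacillus phage phi29
  - Pseudomonas phage phi6
  - Human herpesvirus 6
  - Human herpesvirus 7
  - Shamonda virus
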