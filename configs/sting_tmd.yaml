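# Pore-profiling profile for the STING transmembrane domain (TMD).
#
# The TMD of the human STING dimer (four transmembrane helices per
# protomer) encloses the proton-conducting pore; the ligand-binding domain
# below it is excluded so the profile covers the membrane span only. The
# residue window is this package's interpretation of "the transmembrane
# domain": the published structures do not annotate an exact profiling
# range, so agreement with reported constriction radii is expected within a
# tolerance rather than exactly.
#
# Structures (fetch with scripts/fetch_structures.py, needs network):
#   6nt5.cif  apo human STING            -> constriction ~0.86 A
#   8ik3.cif  cGAMP-bound human STING    -> constriction ~1.71 A
#   7sii.cif  C53-blocked STING          -> pore occluded by the ligand
#             (profile with --include-het to keep C53)
#
# Example:
#   stingquant pore --structure data/structures/8ik3.cif \
#       --residues 1:160 --radius-set hole-simple --step 0.5 \
#       --out results/8ik3_profile.csv

pore:
  residues: [1, 160]     # TMD + juxtamembrane; LBD excluded
  chains: null           # all chains of the dimer
  axis: auto             # principal axis of the TMD selection
  radius_set: hole-simple
  step: 0.5              # A between slices
  grid_spacing: 0.25     # A, coarse search grid
  box_size: 15.0         # A, search window per slice
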