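# Anatomical region map for F1-ATPase subunits, version 1.
#
# Residue intervals (inclusive, PDB numbering) per subunit type.  The head,
# arm, fist, lid, strut, posterior-surface and P-loop anchors are fixed from
# the structure; the torso/foot split at the arginine finger (alpha Arg 373,
# beta Arg 356) and the torso complement are editable defaults.  The P-loop
# nests inside the posterior surface; no other regions overlap.
version: 1
alpha:
  head: [[24, 94]]
  arm: [[116, 150]]
  fist: [[151, 155]]
  strut: [[430, 440]]
  posterior: [[169, 229]]
  p_loop: [[169, 177]]
  torso: [[95, 115], [156, 372]]
  foot: [[373, 510]]
beta:
  head: [[9, 77]]
  arm: [[103, 137]]
  fist: [[138, 143]]
  lid: [[417, 433]]
  posterior: [[157, 214]]
  p_loop: [[156, 163]]
  torso: [[78, 102], [144, 355]]
  foot: [[356, 474]]
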