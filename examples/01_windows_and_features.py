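"""Extract lysine-centered windows from a protein and encode them.

Builds a small protein, cuts the 15-mer window around each lysine, and
shows the dimensionality of the main feature encodings.
"""

from acetylsite import ProteinRecord, encode_fragment, enumerate_lysine_fragments

protein = ProteinRecord("DEMO1", "MSGRGKQGGKARAKAKTRSSRAGLQFPVGRV")

fragments = enumerate_lysine_fragments(protein, n=7)
print(f"{protein.id}: {len(fragments)} lysine-centered 15-mer windows")
for frag in fragments:
    print(f"  K{frag.center:<3d} {frag.window}")

frag = fragments[0]
for scheme in ("AA", "B62", "AAC", "AAPC", "B62+AAPC"):
    vec = encode_fragment(frag, scheme)
    print(f"{scheme:>9s}: {vec.dimension} dimensions")

# Each window is the unit of prediction; '-' pads mark positions beyond
# the protein terminus, and dimensions depend only on the scheme and the
# window length (AA = 21*15, B62 = 20*15, AAC = 20, AAPC = 20*20).
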