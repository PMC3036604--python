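"""The shipped SMARTS dictionary for H-bond donor/acceptor/hydrophobe perception.

One dictionary serves both descriptor counting (rule-of-five) and 3D feature
perception, so the filter and the pharmacophore engine agree on chemistry.

Donors are O/N/S atoms bearing at least one hydrogen (counted per heavy
atom, not per hydrogen).  Acceptors are oxygens with a lone pair (any O not
part of a nitro-type O=N), pyridine-type aromatic nitrogens, nitrile/imine
nitrogens, and H-free sp3 amines not conjugated to an aromatic system or
oxidized.  Hydrophobic atoms are apolar carbons (no polar neighbor,
non-aromatic), thioether sulfurs, and heavy halogens; contiguous clusters
form one hydrophobic feature at their centroid.
"""

HBD_SMARTS = ("[O;!H0]", "[N;!H0]", "[S;!H0]")

HBA_SMARTS = (
    "[O;!$(O=N)]",
    "[$([n;X2;H0])]",
    "[$([N;X1]),$([N;X2;v3;!$(N=O)])]",
    "[$([N;X3;v3;H0;!$(N-a);!$(N~[O,S,P])])]",
)

HBIC_ATOM_SMARTS = "[$([C;!a;!$(C~[N,O,P,S&!v2;!a])]),$([S;v2;X2;H0]),Cl,Br,I]"
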