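name,smiles,letter,class
L-A,C[C@H](N)C(=O)O,A,canonical
L-R,N=C(N)NCCC[C@H](N)C(=O)O,R,canonical
L-N,NC(=O)C[C@H](N)C(=O)O,N,canonical
L-D,N[C@@H](CC(=O)O)C(=O)O,D,canonical
L-C,N[C@@H](CS)C(=O)O,C,canonical
L-E,N[C@@H](CCC(=O)O)C(=O)O,E,canonical
L-Q,NC(=O)CC[C@H](N)C(=O)O,Q,canonical
L-G,NCC(=O)O,G,canonical
L-H,N[C@@H](Cc1c[nH]cn1)C(=O)O,H,canonical
L-I,CC[C@H](C)[C@H](N)C(=O)O,I,canonical
L-L,CC(C)C[C@H](N)C(=O)O,L,canonical
L-K,NCCCC[C@H](N)C(=O)O,K,canonical
L-M,CSCC[C@H](N)C(=O)O,M,canonical
L-F,N[C@@H](Cc1ccccc1)C(=O)O,F,canonical
L-P,O=C(O)[C@@H]1CCCN1,P,canonical
L-S,N[C@@H](CO)C(=O)O,S,canonical
L-T,C[C@@H](O)[C@H](N)C(=O)O,T,canonical
L-W,N[C@@H](Cc1c[nH]c2ccccc12)C(=O)O,W,canonical
L-Y,N[C@@H](Cc1ccc(O)cc1)C(=O)O,Y,canonical
L-V,CC(C)[C@H](N)C(=O)O,V,canonical
N-methyl-alanine,CN[C@@H](C)C(=O)O,A,modified
sarcosine,CNCC(=O)O,G,modified
N-methyl-leucine,CN[C@@H](CC(C)C)C(=O)O,L,modified
N-methyl-phenylalanine,CN[C@@H](Cc1ccccc1)C(=O)O,F,modified
D-alanine,C[C@@H](N)C(=O)O,A,modified
D-valine,CC(C)[C@@H](N)C(=O)O,V,modified
D-lysine,NCCCC[C@@H](N)C(=O)O,K,modified
D-phenylalanine,N[C@H](Cc1ccccc1)C(=O)O,F,modified
N6-acetyl-lysine,CC(=O)NCCCC[C@H](N)C(=O)O,K,modified
4-hydroxy-proline,O=C(O)[C@@H]1C[C@H](O)CN1,P,modified
norleucine,CCCC[C@H](N)C(=O)O,L,modified
ornithine,NCCC[C@H](N)C(=O)O,K,modified
2-aminobutyric-acid,CC[C@H](N)C(=O)O,A,modified
2-aminoisobutyric-acid,CC(C)(N)C(=O)O,A,modified
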