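# Simplified haplogroup marker table for the marker-overlap classifier.
# A deliberately reduced, curated subset of well-known defining variants
# (Phylotree-style, relative to rCRS coordinates) for nine major European
# mtDNA haplogroups. Intended for simulation and testing; for production
# classification load a full Phylotree-derived table with the same columns.
# Alleles are 1-based rCRS positions; parent links form the haplogroup tree
# (empty parent = top level).
# haplogroup	parent	position	ref	alt
H		263	A	G
H		750	A	G
H		1438	A	G
H		4769	A	G
H		8860	A	G
H		15326	A	G
V	H	263	A	G
V	H	750	A	G
V	H	1438	A	G
V	H	4580	G	A
V	H	4769	A	G
V	H	8860	A	G
V	H	15326	A	G
V	H	15904	C	T
J		73	A	G
J		263	A	G
J		295	C	T
J		489	T	C
J		4216	T	C
J		10398	A	G
J		12612	A	G
J		13708	G	A
J		16069	C	T
T		73	A	G
T		263	A	G
T		709	G	A
T		1888	G	A
T		4216	T	C
T		4917	A	G
T		10463	T	C
T		13368	G	A
T		15607	A	G
U		73	A	G
U		263	A	G
U		750	A	G
U		11467	A	G
U		12308	A	G
U		12372	G	A
K	U	73	A	G
K	U	263	A	G
K	U	750	A	G
K	U	1811	A	G
K	U	9055	G	A
K	U	11299	T	C
K	U	11467	A	G
K	U	12308	A	G
K	U	12372	G	A
K	U	14167	C	T
I		73	A	G
I		199	T	C
I		250	T	C
I		263	A	G
I		1719	G	A
I		8251	G	A
I		10034	T	C
I		16391	G	A
W		73	A	G
W		189	A	G
W		204	T	C
W		207	G	A
W		263	A	G
W		1243	T	C
W		5046	G	A
W		8994	G	A
X		73	A	G
X		153	A	G
X		263	A	G
X		1719	G	A
X		6221	T	C
X		6371	C	T
X		14470	T	C
X		16278	C	T
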