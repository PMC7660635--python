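# Raw (unnormalized) physicochemical property values for the 20 standard amino acids.
# Ten properties, two groups of five:
#   polarity, secondary_structure, molecular_volume, codon_diversity,
#   electrostatic_charge -- the five multidimensional factor scores of
#   Atchley et al. (PNAS 2005, 102:6395-6400), Table 2 (factors I-V),
#   which summarize ~500 AAindex scales by factor analysis.
#   hydrophobicity      -- Kyte & Doolittle (J Mol Biol 1982) hydropathy index.
#   side_chain_length   -- number of non-hydrogen atoms in the side chain.
#   helix_propensity    -- Chou & Fasman (1978) alpha-helix propensity P(a).
#   n_codons            -- number of codons in the standard genetic code.
#   strand_propensity   -- Chou & Fasman (1978) beta-strand propensity P(b).
# Values are min-max normalized per property (column) at load time.
aa	polarity	secondary_structure	molecular_volume	codon_diversity	electrostatic_charge	hydrophobicity	side_chain_length	helix_propensity	n_codons	strand_propensity
A	-0.591	-1.302	-0.733	1.570	-0.146	1.8	1	1.42	4	0.83
C	-1.343	0.465	-0.862	-1.020	-0.255	2.5	2	0.70	2	1.19
D	1.050	0.302	-3.656	-0.259	-3.242	-3.5	4	1.01	2	0.54
E	1.357	-1.453	1.477	0.113	-0.837	-3.5	5	1.51	2	0.37
F	-1.006	-0.590	1.891	-0.397	0.412	2.8	7	1.13	2	1.38
G	-0.384	1.652	1.330	1.045	2.064	-0.4	0	0.57	4	0.75
H	0.336	-0.417	-1.673	-1.474	-0.078	-3.2	6	1.00	2	0.87
I	-1.239	-0.547	2.131	0.393	0.816	4.5	4	1.08	3	1.60
K	1.831	-0.561	0.533	-0.277	1.648	-3.9	5	1.16	2	0.74
L	-1.019	-0.987	-1.505	1.266	-0.912	3.8	4	1.21	6	1.30
M	-0.663	-1.524	2.219	-1.005	1.212	1.9	4	1.45	1	1.05
N	0.945	0.828	1.299	-0.169	0.933	-3.5	4	0.67	2	0.89
P	0.189	2.081	-1.628	0.421	-1.392	-1.6	3	0.57	4	0.55
Q	0.931	-0.179	-3.005	-0.503	-1.853	-3.5	5	1.11	2	1.10
R	1.538	-0.055	1.502	0.440	2.897	-4.5	7	0.98	6	0.93
S	-0.228	1.399	-4.760	0.670	-2.647	-0.8	2	0.77	6	0.75
T	-0.032	0.326	2.213	0.908	1.313	-0.7	3	0.83	4	1.19
V	-1.337	-0.279	-0.544	1.242	-1.262	4.2	3	1.06	4	1.70
W	-0.595	0.009	0.672	-2.128	-0.184	-0.9	10	1.08	1	1.37
Y	0.260	0.830	3.097	-0.838	1.512	-1.3	8	0.69	2	1.47
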