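residue,hydropathy_kyte_doolittle,hydrophilicity_hopp_woods,polarity_grantham,polarity_zimmerman,bulkiness_zimmerman,recognition_factors,refractivity,number_of_codons,percent_buried_residues,percent_accessible_residues,average_flexibility,alpha_helix_chou_fasman,beta_sheet_chou_fasman,beta_turn_chou_fasman,coil_deleage_roux,overall_frequency,relative_mutability,molecular_weight,pk_side_chain,net_charge_index,isoelectric_point
A,1.8,-0.5,8.1,0.00,11.50,78,4.34,4,11.2,6.6,0.357,1.42,0.83,0.66,0.824,8.3,100,89.1,0.0,0.0,6.00
C,2.5,-1.0,5.5,1.48,13.46,89,35.77,2,4.1,0.9,0.346,0.70,1.19,1.19,0.953,1.7,20,121.2,8.3,0.0,5.07
D,-3.5,3.0,13.0,49.70,11.68,81,13.28,2,2.9,7.7,0.511,1.01,0.54,1.46,1.197,5.3,106,133.1,3.9,-1.0,2.77
E,-3.5,3.0,12.3,49.90,13.57,78,17.26,2,1.8,5.7,0.497,1.51,0.37,0.74,0.761,6.2,102,147.1,4.1,-1.0,3.22
F,2.8,-2.5,5.2,0.35,19.80,81,29.40,2,5.1,2.4,0.314,1.13,1.38,0.60,0.797,3.9,41,165.2,0.0,0.0,5.48
G,-0.4,0.0,9.0,0.00,3.40,84,0.00,4,11.8,6.7,0.544,0.57,0.75,1.56,1.251,7.2,49,75.1,0.0,0.0,5.97
H,-3.2,-0.5,10.4,51.60,13.69,84,21.81,2,2.0,2.5,0.323,1.00,0.87,0.95,1.068,2.2,66,155.2,6.0,0.1,7.59
I,4.5,-1.8,5.2,0.13,21.40,88,19.06,3,8.6,2.8,0.462,1.08,1.60,0.47,0.886,5.2,96,131.2,0.0,0.0,6.02
K,-3.9,3.0,11.3,49.50,15.71,87,21.29,2,0.05,10.3,0.466,1.16,0.74,1.01,0.897,5.7,56,146.2,10.5,1.0,9.74
L,3.8,-1.8,4.9,0.13,21.40,85,18.78,6,11.7,4.8,0.365,1.21,1.30,0.59,0.670,9.0,40,131.2,0.0,0.0,5.98
M,1.9,-1.3,5.7,1.43,16.25,80,21.64,1,1.9,1.0,0.295,1.45,1.05,0.60,0.810,2.4,94,149.2,0.0,0.0,5.74
N,-3.5,0.2,11.6,3.38,12.82,94,13.28,2,2.9,6.7,0.463,0.67,0.89,1.56,1.167,4.4,134,132.1,0.0,0.0,5.41
P,-1.6,0.0,8.0,1.58,17.43,91,10.93,4,2.7,4.8,0.509,0.57,0.55,1.52,1.540,5.1,56,115.1,0.0,0.0,6.30
Q,-3.5,0.2,10.5,3.53,14.45,87,17.56,2,1.6,5.2,0.493,1.11,1.10,0.98,0.947,4.0,93,146.2,0.0,0.0,5.65
R,-4.5,3.0,10.5,52.00,14.28,95,26.66,6,0.5,4.5,0.529,0.98,0.93,0.95,0.893,5.7,65,174.2,12.5,1.0,10.76
S,-0.8,0.3,9.2,1.67,9.47,107,6.35,6,8.0,9.4,0.507,0.77,0.75,1.43,1.130,6.9,120,105.1,0.0,0.0,5.68
T,-0.7,-0.4,8.6,1.66,15.77,93,11.01,4,4.9,7.0,0.444,0.83,1.19,0.96,1.148,5.8,97,119.1,0.0,0.0,5.60
V,4.2,-1.5,5.9,0.13,21.57,89,13.92,4,12.9,4.5,0.386,1.06,1.70,0.50,0.772,6.6,74,117.1,0.0,0.0,5.96
W,-0.9,-3.4,5.4,2.10,21.67,104,42.53,1,2.2,1.4,0.305,1.08,1.37,0.96,0.941,1.3,18,204.2,0.0,0.0,5.89
Y,-1.3,-2.3,6.2,1.61,18.03,84,31.53,2,2.6,5.1,0.420,0.69,1.47,1.14,1.040,3.2,41,181.2,10.1,0.0,5.66
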