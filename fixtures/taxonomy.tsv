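otu_id	lineage
OTU_0001	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0001
OTU_0002	Bacteria;Tenericutes;Mollicutes;;;Tene_0002
OTU_0003	Bacteria;Firmicutes;Bacilli;;;Firm_0003
OTU_0004	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0004
OTU_0005	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0005
OTU_0006	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0006
OTU_0007	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0007
OTU_0008	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0008
OTU_0009	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0009
OTU_0010	Bacteria;Firmicutes;Bacilli;;;Firm_0010
OTU_0011	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0011
OTU_0012	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0012
OTU_0013	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0013
OTU_0014	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0014
OTU_0015	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0015
OTU_0016	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0016
OTU_0017	Bacteria;Firmicutes;Bacilli;;;Firm_0017
OTU_0018	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0018
OTU_0019	Bacteria;Firmicutes;Bacilli;;;Firm_0019
OTU_0020	Bacteria;Firmicutes;Bacilli;;;Firm_0020
OTU_0021	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0021
OTU_0022	Bacteria;Firmicutes;Bacilli;;;Firm_0022
OTU_0023	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0023
OTU_0024	Bacteria;Tenericutes;Mollicutes;;;Tene_0024
OTU_0025	Bacteria;Tenericutes;Mollicutes;;;Tene_0025
OTU_0026	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0026
OTU_0027	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0027
OTU_0028	Bacteria;Firmicutes;Bacilli;;;Firm_0028
OTU_0029	Bacteria;Firmicutes;Bacilli;;;Firm_0029
OTU_0030	Bacteria;Tenericutes;Mollicutes;;;Tene_0030
OTU_0031	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0031
OTU_0032	Bacteria;Firmicutes;Bacilli;;;Firm_0032
OTU_0033	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0033
OTU_0034	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0034
OTU_0035	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0035
OTU_0036	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0036
OTU_0037	Bacteria;Firmicutes;Bacilli;;;Firm_0037
OTU_0038	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0038
OTU_0039	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0039
OTU_0040	Bacteria;Firmicutes;Bacilli;;;Firm_0040
OTU_0041	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0041
OTU_0042	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0042
OTU_0043	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0043
OTU_0044	Bacteria;Firmicutes;Bacilli;;;Firm_0044
OTU_0045	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0045
OTU_0046	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0046
OTU_0047	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0047
OTU_0048	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0048
OTU_0049	Bacteria;Firmicutes;Bacilli;;;Firm_0049
OTU_0050	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0050
OTU_0051	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0051
OTU_0052	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0052
OTU_0053	Bacteria;Firmicutes;Bacilli;;;Firm_0053
OTU_0054	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0054
OTU_0055	Bacteria;Firmicutes;Bacilli;;;Firm_0055
OTU_0056	Bacteria;Firmicutes;Bacilli;;;Firm_0056
OTU_0057	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0057
OTU_0058	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0058
OTU_0059	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0059
OTU_0060	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0060
OTU_0061	Bacteria;Firmicutes;Bacilli;;;Firm_0061
OTU_0062	Bacteria;Firmicutes;Bacilli;;;Firm_0062
OTU_0063	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0063
OTU_0064	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0064
OTU_0065	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0065
OTU_0066	Bacteria;Firmicutes;Bacilli;;;Firm_0066
OTU_0067	Bacteria;Firmicutes;Bacilli;;;Firm_0067
OTU_0068	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0068
OTU_0069	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0069
OTU_0070	Bacteria;Tenericutes;Mollicutes;;;Tene_0070
OTU_0071	Bacteria;Firmicutes;Bacilli;;;Firm_0071
OTU_0072	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0072
OTU_0073	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0073
OTU_0074	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0074
OTU_0075	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0075
OTU_0076	Bacteria;Firmicutes;Bacilli;;;Firm_0076
OTU_0077	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0077
OTU_0078	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0078
OTU_0079	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0079
OTU_0080	Bacteria;Bacteroidetes;Bacteroidia;;;Bact_0080
OTU_0081	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0081
OTU_0082	Bacteria;Firmicutes;Bacilli;;;Firm_0082
OTU_0083	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0083
OTU_0084	Bacteria;Firmicutes;Bacilli;;;Firm_0084
OTU_0085	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0085
OTU_0086	Bacteria;Firmicutes;Bacilli;;;Firm_0086
OTU_0087	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0087
OTU_0088	Bacteria;Firmicutes;Bacilli;;;Firm_0088
OTU_0089	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0089
OTU_0090	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0090
OTU_0091	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0091
OTU_0092	Bacteria;Firmicutes;Bacilli;;;Firm_0092
OTU_0093	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0093
OTU_0094	Bacteria;Firmicutes;Bacilli;;;Firm_0094
OTU_0095	Bacteria;Firmicutes;Bacilli;;;Firm_0095
OTU_0096	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0096
OTU_0097	Bacteria;Firmicutes;Bacilli;;;Firm_0097
OTU_0098	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0098
OTU_0099	Bacteria;Actinobacteria;Actinomycetia;;;Acti_0099
OTU_0100	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_0100
CONTAM_001	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_001
CONTAM_002	Bacteria;Actinobacteria;Actinomycetia;;;Acti_002
CONTAM_003	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_003
CONTAM_004	Bacteria;Actinobacteria;Actinomycetia;;;Acti_004
CONTAM_005	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_005
CONTAM_006	Bacteria;Actinobacteria;Actinomycetia;;;Acti_006
CONTAM_007	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_007
CONTAM_008	Bacteria;Actinobacteria;Actinomycetia;;;Acti_008
CONTAM_009	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_009
CONTAM_010	Bacteria;Actinobacteria;Actinomycetia;;;Acti_010
CONTAM_011	Bacteria;Proteobacteria;Gammaproteobacteria;;;Prot_011
CONTAM_012	Bacteria;Actinobacteria;Actinomycetia;;;Acti_012
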