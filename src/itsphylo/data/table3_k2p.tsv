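# Pairwise K2P genetic distances among 13 Dendrobium ITS sequences and the
# Pholidota yunnanensis out-group, transcribed from the published
# lower-triangular table (3-decimal precision).
# 1	D. longicorna
# 2	D. infundibulum
# 3	D. trigonopus
# 4	D. bellatulum
# 5	D. williamsonii
# 6	D. cariniferum
# 7	D. sinense
# 8	D. jenkinsii
# 9	D. chrysotoxum
# 10	D. thyrsiflorum
# 11	D. densiflorum
# 12	D. lindleyi
# 13	D. sulcatum
# 14	Pholidota yunnanensis
1
2	0.010
3	0.128 0.123
4	0.026 0.023 0.111
5	0.050 0.047 0.116 0.037
6	0.050 0.047 0.116 0.037 0.003
7	0.020 0.016 0.135 0.032 0.052 0.052
8	0.136 0.132 0.150 0.122 0.132 0.136 0.136
9	0.153 0.149 0.169 0.135 0.151 0.151 0.157 0.175
10	0.120 0.116 0.141 0.107 0.116 0.118 0.124 0.147 0.159
11	0.118 0.114 0.139 0.105 0.114 0.116 0.122 0.143 0.157 0.007
12	0.144 0.142 0.142 0.130 0.140 0.144 0.147 0.064 0.184 0.142 0.138
13	0.124 0.122 0.146 0.111 0.120 0.122 0.126 0.149 0.157 0.098 0.096 0.154
14	0.247 0.246 0.281 0.227 0.241 0.244 0.250 0.282 0.261 0.266 0.264 0.283 0.273
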