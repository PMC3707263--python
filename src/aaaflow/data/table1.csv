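case;sex;L;tau;d_proximal_neck;r;R;D_AMAX;L_AAA
1;M;359,94;320,44;2,8;1,49;2,45;3,945;6,7
2;M;319,5;310,2;1,7;0,67;1,74;2,416;4,1
3;M;216,28;176,8;2,6;1,02;2,03;3,056;8,98
4;M;293,55;255,26;2,6;0,95;3,07;4,031;15,6
5;M;310,34;296,24;2,5;1,25;1,25;2,5;
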