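>RRM1 rnp2=10:6 rnp1=46:8 synthetic reference RRM block
DCDEGAAQPFLFVGNLRYNKVETPGASLEFELESHVGNESEQYCYQKGYGFVHFLAMGSGPLIHRGGLSAVKVFDGIGGDLITDKPEYWR
>RRM2 rnp2=12:6 rnp1=49:8 synthetic reference RRM block
SDKVEGDKKIAPLYVGNLSHAPESKLALEAAPTREKEKWQVTRSLFEARRGFGFVTFDERLAMTPWYQDRSERIVYYRRNDLLLLPSSKSPKEI
>RRM3 rnp2=14:6 rnp1=50:8 synthetic reference RRM block
TNPLGKREYADLARIFVGGLCTTAIDDFINGTGTANFQYVLQFGDTISGGKGFGFVRFSYSGKFAYFKTSLILVEGMTVQKIMTNRQEDAL
>RRM4 rnp2=14:6 rnp1=47:8 synthetic reference RRM block
FYGRQSGDAALLQIVFVGRLLVLDVNVAEWTATSGLKYIESAESFDERGYAFVEFGYTVNKRNRILVNVNGSVDYTGKCVKADEIYMTSLVVFY
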