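# deviation fixture schedule: per-subunit hinge rotations
# (deg; a rigid face-tetramer tilt about an in-plane axis
# through the face center composed with an individual tilt
# about a parallel axis through the subunit base) and
# per-edge bending deltas (deg), calibrated once so the
# measured statistics are a 9 deg mean face tilt, a 17 deg
# max subunit tilt (cap subunits largest, tilt order matching
# displacement order) and bending angles spanning 81-89 deg.
# Regenerate with scripts/build_fixture.py
meta	sigma	0.1
meta	noise_seed	314159
tilt	0	8.3448043804	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 75.000000
tilt	0	-0.7721764095	0.000000000000 1.000000000000 0.000000000000	-20.000000 -30.000000 40.468750
tilt	0	-3.5807463384	0.419599295269 0.907709442173 -0.000000000000	-20.000000 -30.000000 40.468750
tilt	1	9.1513375921	1.000000000000 0.000000000000 0.000000000000	0.000000 75.000000 0.000000
tilt	1	0.1226994222	1.000000000000 0.000000000000 0.000000000000	-20.000000 40.468750 30.000000
tilt	1	-3.7686390509	0.984926347339 -0.000000000000 -0.172974247553	-20.000000 40.468750 30.000000
tilt	2	2.3806781213	1.000000000000 0.000000000000 0.000000000000	0.000000 -75.000000 0.000000
tilt	2	15.8811898514	1.000000000000 0.000000000000 0.000000000000	-20.000000 -40.468750 -30.000000
tilt	3	5.4655239635	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 -75.000000
tilt	3	0.2886498038	0.000000000000 1.000000000000 0.000000000000	-20.000000 30.000000 -40.468750
tilt	3	0.3521699264	-0.551382430702 0.834252608694 -0.000000000000	-20.000000 30.000000 -40.468750
tilt	4	5.4655239635	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 -75.000000
tilt	4	12.7102064799	0.000000000000 1.000000000000 0.000000000000	-30.000000 -20.000000 -40.468750
tilt	5	9.1513375921	1.000000000000 0.000000000000 0.000000000000	0.000000 75.000000 0.000000
tilt	5	-2.3415192240	1.000000000000 0.000000000000 0.000000000000	-30.000000 40.468750 -20.000000
tilt	5	-5.6750386304	0.986162298737 0.000000000000 -0.165782751059	-30.000000 40.468750 -20.000000
tilt	6	2.3806781213	1.000000000000 0.000000000000 0.000000000000	0.000000 -75.000000 0.000000
tilt	6	3.5230913996	1.000000000000 0.000000000000 0.000000000000	-30.000000 -40.468750 20.000000
tilt	6	0.0962390471	0.999629996470 0.000000000000 0.027200554340	-30.000000 -40.468750 20.000000
tilt	7	8.3448043804	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 75.000000
tilt	7	-1.7608692597	0.000000000000 1.000000000000 0.000000000000	-30.000000 20.000000 40.468750
tilt	7	-2.7445272871	0.321931151687 0.946763082071 -0.000000000000	-30.000000 20.000000 40.468750
tilt	8	1.5184318939	0.000000000000 0.000000000000 1.000000000000	75.000000 0.000000 0.000000
tilt	8	2.4063579714	0.000000000000 0.000000000000 1.000000000000	40.468750 -20.000000 -30.000000
tilt	8	-1.2790561233	0.000000000000 -0.271964793014 0.962307202176	40.468750 -20.000000 -30.000000
tilt	9	1.5184318939	0.000000000000 0.000000000000 1.000000000000	75.000000 0.000000 0.000000
tilt	9	1.5837221053	0.000000000000 0.000000000000 1.000000000000	40.468750 -30.000000 20.000000
tilt	9	1.5383764500	0.000000000000 -0.249519532970 0.968369765465	40.468750 -30.000000 20.000000
tilt	10	1.5184318939	0.000000000000 0.000000000000 1.000000000000	75.000000 0.000000 0.000000
tilt	10	4.2819714730	0.000000000000 0.000000000000 1.000000000000	40.468750 30.000000 -20.000000
tilt	10	3.1975093648	0.000000000000 -0.900513460269 0.434828136019	40.468750 30.000000 -20.000000
tilt	11	1.5184318939	0.000000000000 0.000000000000 1.000000000000	75.000000 0.000000 0.000000
tilt	11	21.4691724651	0.000000000000 0.000000000000 1.000000000000	40.468750 20.000000 30.000000
tilt	12	5.8965636598	0.000000000000 0.000000000000 1.000000000000	-75.000000 0.000000 0.000000
tilt	12	-1.9821580262	0.000000000000 0.000000000000 1.000000000000	-40.468750 -20.000000 30.000000
tilt	12	-1.0337190024	-0.000000000000 0.395685005090 0.918386289503	-40.468750 -20.000000 30.000000
tilt	13	5.8965636598	0.000000000000 0.000000000000 1.000000000000	-75.000000 0.000000 0.000000
tilt	13	9.7503453223	0.000000000000 0.000000000000 1.000000000000	-40.468750 -30.000000 -20.000000
tilt	14	5.8965636598	0.000000000000 0.000000000000 1.000000000000	-75.000000 0.000000 0.000000
tilt	14	-1.4078498486	0.000000000000 0.000000000000 1.000000000000	-40.468750 30.000000 20.000000
tilt	14	-2.7971644119	-0.000000000000 0.266308322904 0.963887896569	-40.468750 30.000000 20.000000
tilt	15	5.8965636598	0.000000000000 0.000000000000 1.000000000000	-75.000000 0.000000 0.000000
tilt	15	-3.7274542117	0.000000000000 0.000000000000 1.000000000000	-40.468750 20.000000 -30.000000
tilt	15	-1.7233490400	-0.000000000000 0.742945109671 0.669352346688	-40.468750 20.000000 -30.000000
tilt	16	8.3448043804	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 75.000000
tilt	16	-4.9319317425	0.000000000000 1.000000000000 0.000000000000	30.000000 -20.000000 40.468750
tilt	16	-2.5055682518	0.554945793159 0.831886510682 -0.000000000000	30.000000 -20.000000 40.468750
tilt	17	9.1513375921	1.000000000000 0.000000000000 0.000000000000	0.000000 75.000000 0.000000
tilt	17	7.2783400374	1.000000000000 0.000000000000 0.000000000000	30.000000 40.468750 20.000000
tilt	18	2.3806781213	1.000000000000 0.000000000000 0.000000000000	0.000000 -75.000000 0.000000
tilt	18	0.5352921060	1.000000000000 0.000000000000 0.000000000000	30.000000 -40.468750 -20.000000
tilt	18	-0.3962972924	0.615744146007 0.000000000000 0.787946157207	30.000000 -40.468750 -20.000000
tilt	19	5.4655239635	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 -75.000000
tilt	19	-1.8338195925	0.000000000000 1.000000000000 0.000000000000	30.000000 20.000000 -40.468750
tilt	19	-3.2332477939	-0.280598221277 0.959825316511 0.000000000000	30.000000 20.000000 -40.468750
tilt	20	5.4655239635	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 -75.000000
tilt	20	-2.5512037299	0.000000000000 1.000000000000 0.000000000000	20.000000 -30.000000 -40.468750
tilt	20	-2.6091740309	0.452854043230 0.891584665374 0.000000000000	20.000000 -30.000000 -40.468750
tilt	21	9.1513375921	1.000000000000 0.000000000000 0.000000000000	0.000000 75.000000 0.000000
tilt	21	-4.9993326698	1.000000000000 0.000000000000 0.000000000000	20.000000 40.468750 -30.000000
tilt	21	-5.1616972419	0.766759844038 -0.000000000000 0.641934063258	20.000000 40.468750 -30.000000
tilt	22	2.3806781213	1.000000000000 0.000000000000 0.000000000000	0.000000 -75.000000 0.000000
tilt	22	5.3741985411	1.000000000000 0.000000000000 0.000000000000	20.000000 -40.468750 30.000000
tilt	22	-1.7849251232	0.966776415485 -0.000000000000 0.255623477915	20.000000 -40.468750 30.000000
tilt	23	8.3448043804	0.000000000000 1.000000000000 0.000000000000	0.000000 0.000000 75.000000
tilt	23	5.4807876082	0.000000000000 1.000000000000 0.000000000000	20.000000 30.000000 40.468750
bend	+x|+y	11.7099827940
bend	+x|+z	-1.6901093279
bend	+x|-y	-3.0563935065
bend	+x|-z	2.1216105241
bend	+y|+z	3.4667329185
bend	+y|-z	4.4301334595
bend	-x|+y	2.6265674388
bend	-x|+z	-2.2524740872
bend	-x|-y	0.5472595395
bend	-x|-z	6.5857721971
bend	-y|+z	-5.7062557805
bend	-y|-z	3.9952101810
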