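measure_id,label,domain,reversed,periods,units,source
parent_smi,Proportion of parents enrolled in Medicaid with a primary SMI diagnosis,family_stability,False,period_2,proportion,Medicaid claims
child_poverty,Proportion of children living in a household with below-poverty income,family_stability,False,period_1;period_2,proportion,ACS
no_father_on_birth,Proportion of births that include no father's first/middle/last name,family_stability,False,period_1;period_2,proportion,vital statistics
parent_sud,Proportion of families with a parent served by Medicaid who has an SUD diagnosis,family_stability,False,period_2,proportion,Medicaid claims
labor_market_engagement,Labor Market Engagement Index,family_stability,True,period_1;period_2,index,HUD
infant_mortality,Proportion of births that resulted in an infant mortality,infant_health,False,period_1;period_2,proportion,vital statistics
infant_injury,Proportion of Medicaid infants who had an injury or poisoning in the first year of life,infant_health,False,period_2,proportion,Medicaid claims
infant_nas,Proportion of Medicaid-enrolled infants with neonatal abstinence syndrome,infant_health,False,period_2,proportion,Medicaid claims
infant_nicu,Proportion of Medicaid-enrolled infants with NICU stay,infant_health,False,period_2,proportion,Medicaid claims
preterm_birth,Proportion of infants born preterm,infant_health,False,period_1;period_2,proportion,vital statistics
well_child_15mo,Proportion of Medicaid children with six or more well-child visits in first 15 months of life,infant_health,True,period_1;period_2,proportion,Medicaid claims
severe_maternal_morbidity,Proportion of infants born to Medicaid-enrolled women with severe maternal morbidity,infant_health,False,period_2,proportion,Medicaid claims
developmental_delay_1_5,Proportion of Medicaid-enrolled children ages 1-5 with a diagnosis of developmental delay,children_health,False,period_2,proportion,Medicaid claims
well_child_3_6,Proportion of Medicaid children age 3-6 with one or more well-child visits with a PCP,children_health,True,period_2,proportion,Medicaid claims
asthma_6_17,Proportion of Medicaid-enrolled children ages 6-17 with a diagnosis of asthma,children_health,False,period_1;period_2,proportion,Medicaid claims
mental_illness_6_17,Percent of children ages 6-17 with a diagnosis of mental illness,children_health,False,period_1;period_2,proportion,Medicaid claims
developmental_disability_6_17,Proportion of children ages 6-17 with a diagnosis of a developmental disability,children_health,False,period_2,proportion,Medicaid claims
diabetes_6_17,Proportion of children ages 6-17 with a diagnosis of diabetes,children_health,False,period_2,proportion,Medicaid claims
psychotropic_bh_med,Proportion of children ages 6-17 who received psychotropic BH medication,children_health,False,period_2,proportion,Medicaid claims
obesity_6_17,Proportion of children ages 6-17 with a diagnosis of obesity,children_health,False,period_1;period_2,proportion,Medicaid claims
bh_access_standards,Proportion of Medicaid behavioral health visits for children that meet CMS access standards,access,True,period_2,proportion,Medicaid claims
pcp_access_standards,Proportion of primary care visits for children that meet CMS access standards,access,True,period_2,proportion,Medicaid claims
geographic_isolation,Geographic isolation (rurality) of the census tract,access,False,period_1;period_2,z-score,USDA-ERS
low_transportation_cost,Low Transportation Cost Index,access,True,period_1;period_2,index,HUD
no_vehicle,Percent occupied housing units in tract without a vehicle,access,False,period_1;period_2,percent,ACS
supermarket_distance,Percent tract population within a distance from the supermarket,access,False,period_1;period_2,percent,USDA-ERS
elementary_school_distance,Distance to nearest elementary school,access,False,period_1;period_2,z-score,GIS
youth_dropout,Percent youth who have dropped out,education,False,period_1;period_2,percent,ACS
adults_no_hs,Percent of adults in the tract with less than high school education,education,False,period_1;period_2,percent,ACS
youth_not_enrolled,Percent of youth (age 5-17) not enrolled in school,education,False,period_1;period_2,proportion,ACS
third_grade_reading,Proportion of children not meeting third grade reading standards,education,False,period_1;period_2,proportion,education report card
free_lunch,Free lunch distribution,education,True,period_2,z-score,education report card
graduation_rate,Graduation rate,education,True,period_2,z-score,education report card
school_performance,School performance index,education,True,period_2,z-score,education report card
school_value_added,School's value-added score,education,True,period_1;period_2,z-score,education report card
mortgage_burden_50,Percentage putting 50 percent of income toward mortgage,housing,False,period_1;period_2,percent,ACS
low_occupancy,Percentage of households with less than one person per room,housing,False,period_1;period_2,percent,ACS
rent_burden_50,Percentage putting 50 percent of income toward rent,housing,False,period_1;period_2,percent,ACS
vacant_housing,Percent housing identified as vacant,housing,False,period_1;period_2,percent,ACS
pct_renting,Percentage renting,housing,False,period_1;period_2,percent,ACS
residential_instability,Percentage living in same housing unit for less than 1 year,housing,False,period_1;period_2,percent,ACS
eviction_rate,Rate of evictions among renters,housing,False,period_1;period_2,rate,eviction records
no_vegetation,Tract land area not covered by vegetation,environment,False,period_1;period_2,percent,NHGIS
open_development,Tract land area covered by open development,environment,False,period_1;period_2,proportion,NHGIS
pre1980_housing,Percent of housing units constructed prior to 1980,environment,False,period_1;period_2,percent,ACS
pm25,Annual average of daily PM2.5 measurements,environment,False,period_1;period_2,index,EPA
tobacco_retail,Count of tobacco retail outlets within a 3/4 mile buffered tract boundary,environment,False,period_1;period_2,count,retail licensure
env_health_hazard,Environmental Health Hazard Index,environment,True,period_1;period_2,index,HUD
violent_crime,Average annual homicide assault and sexual assault incidents per person,criminal_justice,False,period_1;period_2,rate,incident reports
robbery,Average annual robbery incidents per person,criminal_justice,False,period_1;period_2,rate,incident reports
property_crime,Average annual burglary larceny-theft and motor-vehicle theft incidents per person,criminal_justice,False,period_1;period_2,rate,incident reports
dui_drunkenness,Average annual drunkenness and DUI incidents per person,criminal_justice,False,period_1;period_2,rate,incident reports
drug_crime,Average annual drug crime incidents per person,criminal_justice,False,period_1;period_2,rate,incident reports
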